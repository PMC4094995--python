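"""LP construction and the parametric objective delta*f_b - sum(c_r f_r)."""

import random

import numpy as np
import pytest

from fastgapfill import (
    DEFAULT_SCHEME,
    CandidatePool,
    CandidateReaction,
    MetabolicModel,
    Metabolite,
    Reaction,
    add_decoys,
    build_lp,
    knockout,
    make_chain_model,
    maximize_biomass,
    prepare,
)
from fastgapfill.lp import export_lp_text


def counting_model_and_pool():
    """3 metabolites; 4 reactions incl. biomass, plus 1 uptake; pool of 2."""
    model = MetabolicModel.create(
        metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C")],
        reactions=[
            Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0}),
            Reaction(id="R2", stoichiometry={"B": -1.0, "C": 1.0}),
            Reaction(id="R3", stoichiometry={"C": -1.0, "A": 1.0}),
            Reaction(id="BM", stoichiometry={"C": -0.5}, kind="biomass"),
            Reaction(id="EX_A_in", stoichiometry={"A": 1.0}, kind="exchange",
                     upper_bound=16.0),
        ],
        biomass_id="BM",
        nutrients={"A": 16.0},
    )
    pool = CandidatePool.create(
        [
            CandidateReaction(
                Reaction(id="P1", stoichiometry={"A": -1.0, "C": 1.0}), cost=5.0
            ),
            CandidateReaction(
                Reaction(id="P2", stoichiometry={"B": -1.0, "A": 1.0}), cost=1.0
            ),
        ]
    )
    return model, pool


def test_lp_dimensions_one_variable_per_reaction_one_row_per_metabolite():
    model, pool = counting_model_and_pool()
    lp = build_lp(model, pool)
    assert lp.n_variables == 7
    assert lp.n_constraints == 3


def test_empty_pool_reduces_to_plain_fba(t1_complete):
    lp = build_lp(t1_complete)
    sol = lp.solve_at(1.0)
    ref = maximize_biomass(t1_complete)
    assert sol.optimal
    assert sol.biomass_flux == pytest.approx(ref.biomass_flux, abs=1e-6)
    assert sol.biomass_flux > 0


def test_disconnected_candidates_carry_no_flux(t1_complete):
    pool = CandidatePool.create(
        [
            CandidateReaction(
                Reaction(id=f"D{i}", stoichiometry={f"ghost{i}": -1.0, f"ghost{i}b": 1.0}),
                cost=1.0,
            )
            for i in range(3)
        ]
    )
    lp = build_lp(t1_complete, pool)
    sol = lp.solve_at(3.0)
    assert sol.optimal and sol.biomass_flux > 0
    assert all(sol.fluxes[f"D{i}"] == pytest.approx(0.0, abs=1e-9) for i in range(3))


def test_delta_zero_gives_zero_objective_and_inactive_candidates(t1):
    model, pool, _ = t1
    lp = build_lp(model, pool)
    sol = lp.solve_at(0.0)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
    assert all(sol.fluxes[rid] == pytest.approx(0.0, abs=1e-9)
               for rid in lp.candidate_ids)


def test_complete_model_at_high_delta_ignores_penalized_candidates(t1_complete):
    # candidates shadowing existing routes add only penalty, so the optimum
    # routes all flux through the free model reactions
    pool = CandidatePool.create(
        [
            CandidateReaction(
                Reaction(id="ALT_R1", stoichiometry={"M0": -1.0, "M1": 1.0}), cost=5.0
            ),
            CandidateReaction(
                Reaction(id="ALT_B", stoichiometry={"M1": -1.0, "M2": 1.0}), cost=1.0
            ),
        ]
    )
    lp = build_lp(t1_complete, pool)
    sol = lp.solve_at(float(len(pool)))
    ref = maximize_biomass(t1_complete)
    assert sol.biomass_flux == pytest.approx(ref.biomass_flux, abs=1e-6)
    assert all(sol.fluxes[rid] <= 1e-8 for rid in lp.candidate_ids)


def test_negative_delta_rejected(t1):
    model, pool, _ = t1
    with pytest.raises(ValueError):
        build_lp(model, pool).solve_at(-1.0)


def test_unassigned_candidate_cost_is_an_error(t1_complete):
    pool = CandidatePool.create(
        [CandidateReaction(Reaction(id="P", stoichiometry={"M0": -1.0}), cost=None)]
    )
    with pytest.raises(ValueError, match="cost"):
        build_lp(t1_complete, pool)


@pytest.mark.parametrize("seed", range(4))
def test_biomass_flux_is_nondecreasing_in_delta(seed):
    """A larger biomass reward never reduces the achievable rewarded biomass."""
    rng = random.Random(seed)
    complete = make_chain_model(rng.randint(5, 12), rng.randint(1, 3), seed)
    targets = {rng.choice(sorted(set(complete.reactions) - {"BIOMASS"}))}
    incomplete, pool = knockout(complete, targets)
    pool = add_decoys(pool, incomplete, rng.randint(2, 10), seed)
    model, pool = prepare(incomplete, pool, scheme=DEFAULT_SCHEME)
    lp = build_lp(model, pool)
    deltas = sorted(rng.uniform(0, len(pool)) for _ in range(6))
    fluxes = [lp.solve_at(d).biomass_flux for d in deltas]
    assert all(b >= a - 1e-6 for a, b in zip(fluxes, fluxes[1:]))


def test_reused_template_matches_fresh_build(t1):
    model, pool, _ = t1
    lp = build_lp(model, pool)
    for delta in (0.5, 1.5, 3.0):
        again = build_lp(model, pool).solve_at(delta)
        reused = lp.solve_at(delta)
        assert reused.biomass_flux == pytest.approx(again.biomass_flux, abs=1e-6)
        assert reused.objective_value == pytest.approx(again.objective_value, abs=1e-6)


def test_steady_state_residual_within_tolerance(t1):
    model, pool, _ = t1
    sol = build_lp(model, pool).solve_at(2.0)
    assert sol.optimal
    assert sol.balance_residual <= 1e-6
    assert all(f >= 0.0 for f in sol.fluxes.values())


def test_unpreprocessed_input_rejected():
    model = MetabolicModel.create(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction(id="R", stoichiometry={"A": -1.0, "B": 1.0},
                     reversible=True, lower_bound=-5.0),
            Reaction(id="BM", stoichiometry={"B": -1.0}, kind="biomass"),
        ],
        biomass_id="BM",
    )
    with pytest.raises(ValueError, match="LP-ready"):
        build_lp(model)


def test_lp_text_export_mentions_all_variables(t1):
    model, pool, _ = t1
    lp = build_lp(model, pool)
    text = export_lp_text(lp, 2.0)
    assert text.startswith("Maximize")
    for rid in lp.reaction_ids:
        assert rid in text
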