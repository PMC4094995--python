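"""Reversible splitting, generic-reaction instantiation and environment
attachment."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastgapfill import (
    CandidatePool,
    CandidateReaction,
    ClassMap,
    MetabolicModel,
    Metabolite,
    Reaction,
    attach_environment,
    instantiate_generic,
    make_chain_model,
    maximize_biomass,
    prepare,
    split_reversible,
    split_reversible_pool,
)
from fastgapfill.config import FLUX_CAP

from conftest import free_sign_max_biomass


class TestSplitReversible:
    def test_irreversible_reactions_pass_through(self):
        r = Reaction(id="R", stoichiometry={"A": -1.0, "B": 1.0}, upper_bound=10.0)
        assert split_reversible([r]) == [r]

    def test_sign_bookkeeping_of_bounds_and_stoichiometry(self):
        r = Reaction(
            id="R", stoichiometry={"A": -1.0, "B": 1.0},
            reversible=True, lower_bound=-5.0, upper_bound=10.0,
        )
        fwd, rev = split_reversible([r])
        assert fwd.id == "R_fwd" and rev.id == "R_rev"
        assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 10.0)
        assert (rev.lower_bound, rev.upper_bound) == (0.0, 5.0)
        assert fwd.stoichiometry == {"A": -1.0, "B": 1.0}
        assert rev.stoichiometry == {"A": 1.0, "B": -1.0}
        assert not fwd.reversible and not rev.reversible

    def test_pool_split_inherits_full_parent_cost(self):
        pool = CandidatePool.create(
            CandidateReaction(
                Reaction(id=f"C{i}", stoichiometry={"A": -1.0, "B": 1.0},
                         reversible=True, lower_bound=-1.0),
                cost=5.0,
            )
            for i in range(3)
        )
        split = split_reversible_pool(pool)
        assert len(split) == 6
        assert all(c.cost == 5.0 for c in split)

    @given(
        lb=st.floats(min_value=-50.0, max_value=0.0),
        ub=st.floats(min_value=0.0, max_value=50.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_split_bounds_cover_the_signed_flux_range(self, lb, ub):
        """Any signed flux v in [lb, ub] decomposes into fwd - rev with both
        parts inside the derived non-negative bounds, and vice versa."""
        r = Reaction(id="R", stoichiometry={"A": -1.0, "B": 1.0},
                     reversible=True, lower_bound=lb, upper_bound=ub)
        fwd, rev = split_reversible([r])
        assert fwd.lower_bound == rev.lower_bound == 0.0
        assert fwd.upper_bound == ub
        assert rev.upper_bound == (-lb if lb < 0 else ub)
        # extremes of the original range are representable
        assert 0.0 <= ub <= fwd.upper_bound
        assert 0.0 <= -min(lb, 0.0) <= rev.upper_bound

    def test_derived_id_collision_is_an_error(self):
        rxns = [
            Reaction(id="R", stoichiometry={"A": -1.0}, reversible=True,
                     lower_bound=-1.0),
            Reaction(id="R_fwd", stoichiometry={"A": -1.0}),
        ]
        with pytest.raises(ValueError, match="R_fwd"):
            split_reversible(rxns)

    @pytest.mark.parametrize("seed", range(5))
    def test_split_preserves_max_biomass(self, seed):
        """Splitting reversible reactions must not change the FBA optimum,
        checked against a free-sign LP that keeps signed fluxes."""
        rng = random.Random(seed)
        model = make_chain_model(rng.randint(4, 10), rng.randint(1, 3), seed)
        model = attach_environment(model)
        # make a random subset of the interior reactions reversible
        for rid, r in model.reactions.items():
            if r.kind == "enzymatic" and rng.random() < 0.5:
                r.reversible = True
                r.lower_bound = -rng.choice((1.0, 5.0, r.upper_bound))
        oracle = free_sign_max_biomass(model)
        split_model = model.copy()
        split_model.reactions = {
            r.id: r for r in split_reversible(model.reactions.values())
        }
        ours = maximize_biomass(split_model)
        assert ours.optimal
        assert ours.biomass_flux == pytest.approx(oracle, abs=1e-6)


class TestInstantiateGeneric:
    def test_reaction_without_class_refs_is_identity(self):
        cm = ClassMap(members={"ClassX": ["m1", "m2"]})
        r = Reaction(id="R", stoichiometry={"A": -1.0, "B": 1.0})
        assert instantiate_generic(r, cm) == [r]

    def test_single_class_enumerates_members(self):
        cm = ClassMap(members={"ClassX": ["m1", "m2"]})
        r = Reaction(id="R", stoichiometry={"ClassX": -1.0, "A": -1.0, "B": 1.0})
        out = instantiate_generic(r, cm)
        assert {o.id for o in out} == {"R__m1", "R__m2"}
        stoichs = sorted(tuple(sorted(o.stoichiometry.items())) for o in out)
        assert stoichs == [
            (("A", -1.0), ("B", 1.0), ("m1", -1.0)),
            (("A", -1.0), ("B", 1.0), ("m2", -1.0)),
        ]

    def test_linked_classes_substitute_in_lockstep(self):
        # hand-written 2x2 substitution table: only the diagonal pairs
        # (m1, m1p) and (m2, m2p) are chemically coherent
        cm = ClassMap(
            members={"ClassX": ["m1", "m2"], "ClassXP": ["m1p", "m2p"]},
            linked=[("ClassX", "ClassXP")],
        )
        r = Reaction(id="PHOS", stoichiometry={"ClassX": -1.0, "ClassXP": 1.0})
        out = instantiate_generic(r, cm)
        table = {tuple(sorted(o.stoichiometry.items())) for o in out}
        assert table == {
            (("m1", -1.0), ("m1p", 1.0)),
            (("m2", -1.0), ("m2p", 1.0)),
        }

    def test_independent_classes_take_cartesian_product(self):
        cm = ClassMap(members={"CA": ["a1", "a2", "a3"], "CB": ["b1", "b2"]})
        r = Reaction(id="R", stoichiometry={"CA": -1.0, "CB": 1.0})
        out = instantiate_generic(r, cm)
        assert len(out) == 6  # product of member counts
        assert len({o.id for o in out}) == 6

    def test_empty_class_drops_reaction(self):
        cm = ClassMap(members={"ClassX": []})
        r = Reaction(id="R", stoichiometry={"ClassX": -1.0, "B": 1.0})
        assert instantiate_generic(r, cm) == []

    def test_unequal_linked_member_counts_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            ClassMap(members={"CA": ["a1"], "CB": ["b1", "b2"]},
                     linked=[("CA", "CB")])


class TestAttachEnvironment:
    def _model(self, nutrients, secretions=()):
        return MetabolicModel.create(
            metabolites=[Metabolite("glc"), Metabolite("co2"), Metabolite("bm")],
            reactions=[
                Reaction(id="R", stoichiometry={"glc": -1.0, "bm": 1.0, "co2": 1.0}),
                Reaction(id="BM", stoichiometry={"bm": -1.0}, kind="biomass"),
            ],
            biomass_id="BM",
            nutrients=nutrients,
            secretions=secretions,
        )

    @pytest.mark.parametrize("cap", [16.0, 12.0])
    def test_uptake_cap_becomes_exchange_upper_bound(self, cap):
        out = attach_environment(self._model({"glc": cap}, {"co2"}))
        assert out.reactions["EX_glc_in"].upper_bound == cap
        assert out.reactions["EX_glc_in"].stoichiometry == {"glc": 1.0}
        assert out.reactions["EX_co2_out"].stoichiometry == {"co2": -1.0}
        assert out.reactions["EX_co2_out"].upper_bound == FLUX_CAP

    def test_uncapped_nutrient_gets_finite_sentinel_bound(self):
        out = attach_environment(self._model({"glc": None}))
        assert out.reactions["EX_glc_in"].upper_bound == FLUX_CAP

    def test_idempotent(self):
        once = attach_environment(self._model({"glc": 16.0}, {"co2"}))
        twice = attach_environment(once)
        assert set(twice.reactions) == set(once.reactions)

    def test_empty_environment_means_no_growth(self):
        out = attach_environment(self._model({}))
        assert all(r.kind != "exchange" for r in out.reactions.values())
        sol = maximize_biomass(out)
        assert sol.optimal and sol.biomass_flux == pytest.approx(0.0, abs=1e-9)

    def test_unknown_nutrient_rejected(self):
        model = self._model({"glc": 16.0})
        model.nutrients["GHOST"] = 1.0
        with pytest.raises(ValueError, match="GHOST"):
            attach_environment(model)


def test_prepare_pipeline_produces_lp_ready_inputs(t1):
    model, pool, removed = t1
    assert all(not r.reversible and r.lower_bound >= 0
               for r in model.reactions.values())
    assert any(r.kind == "exchange" for r in model.reactions.values())
    assert all(c.cost is not None for c in pool)
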