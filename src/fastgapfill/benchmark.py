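"""Benchmark protocol: generate knockout instances, gap-fill them, and
measure soundness, iteration counts and agreement with the exact oracle.

This reproduces, on synthetic networks, the evaluation design used for
gap-fillers: remove reactions from a working model until growth stops,
offer them back inside a large candidate pool, and check what the
heuristic suggests against the exact minimum-cost answer.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from .config import DEFAULT_TOLERANCES, Tolerances
from .costs import DEFAULT_SCHEME, CostScheme
from .gapfill import fast_gap_filling, iteration_count
from .milp import milp_gap_fill
from .model import CandidatePool, CandidateReaction, MetabolicModel
from .preprocess import prepare
from .synth import (
    add_decoys,
    benchmark_instances,
    knockout,
    make_chain_model,
    make_low_flux_fixture,
    realize_instance,
)
from .verify import prune_low_flux, verify_solution


def enumerate_min_cost(
    model: MetabolicModel,
    pool: CandidatePool,
    tol: Tolerances = DEFAULT_TOLERANCES,
) -> tuple[float | None, frozenset[str] | None]:
    """Exhaustive minimum-cost completion by subset enumeration.

    Ground truth for tiny pools (exponential in |M|): checks each subset
    with a plain FBA solve, skipping subsets that cannot beat the
    incumbent cost.  Returns ``(None, None)`` when nothing completes.
    """
    ids = sorted(pool.ids())
    best_cost, best_set = None, None
    for k in range(len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            cost = sum(pool.cost_of(rid) for rid in combo)
            if best_cost is not None and cost >= best_cost:
                continue
            if verify_solution(model, pool, combo, tol=tol):
                best_cost, best_set = cost, frozenset(combo)
    return best_cost, best_set


@dataclass
class SweepResult:
    """Aggregate of a soundness sweep over generated instances."""

    n_instances: int = 0
    n_feasible: int = 0
    n_bound_ok: int = 0
    n_solutions: int = 0
    n_sound: int = 0
    pool_sizes: list[int] = field(default_factory=list)

    @property
    def soundness_pct(self) -> float:
        return 100.0 * self.n_sound / self.n_solutions if self.n_solutions else 0.0

    @property
    def bound_pct(self) -> float:
        return 100.0 * self.n_bound_ok / self.n_instances if self.n_instances else 0.0


def soundness_sweep(
    seed: int,
    n_instances: int = 50,
    scheme: CostScheme = DEFAULT_SCHEME,
) -> SweepResult:
    """Gap-fill every generated instance and verify every returned set."""
    out = SweepResult()
    for spec in benchmark_instances(seed, n_instances):
        incomplete, pool, _removed = realize_instance(spec)
        model, pool = prepare(incomplete, pool, scheme=scheme)
        run = fast_gap_filling(model, pool)
        out.n_instances += 1
        out.pool_sizes.append(len(pool))
        out.n_feasible += run.feasible
        out.n_bound_ok += run.n_lp_solves <= iteration_count(len(pool))
        for sol in run.solutions:
            out.n_solutions += 1
            out.n_sound += verify_solution(model, pool, sol)
    return out


@dataclass
class OracleComparison:
    n_instances: int = 0
    n_milp_matches_enumeration: int = 0
    n_heuristic_dominated: int = 0  # FGF best cost >= MILP cost

    @property
    def milp_match_pct(self) -> float:
        return (100.0 * self.n_milp_matches_enumeration / self.n_instances
                if self.n_instances else 0.0)

    @property
    def dominance_pct(self) -> float:
        return (100.0 * self.n_heuristic_dominated / self.n_instances
                if self.n_instances else 0.0)


def oracle_comparison(
    seed: int,
    n_instances: int = 6,
    max_pool: int = 10,
    scheme: CostScheme = DEFAULT_SCHEME,
) -> OracleComparison:
    """Small-pool instances: MILP vs exhaustive enumeration vs heuristic."""
    rng = random.Random(seed)
    out = OracleComparison()
    for _ in range(n_instances):
        inst_seed = rng.randrange(2**31)
        inst_rng = random.Random(inst_seed)
        complete = make_chain_model(
            inst_rng.randint(5, 9), inst_rng.randint(1, 2), inst_seed
        )
        knockable = sorted(set(complete.reactions) - {complete.biomass_id})
        targets = set(inst_rng.sample(knockable, inst_rng.randint(1, 2)))
        incomplete, pool = knockout(complete, targets)
        n_decoys = inst_rng.randint(2, max_pool - len(targets))
        pool = add_decoys(pool, incomplete, n_decoys, inst_seed + 1)
        model, pool = prepare(incomplete, pool, scheme=scheme)

        milp_res = milp_gap_fill(model, pool)
        enum_cost, _ = enumerate_min_cost(model, pool)
        run = fast_gap_filling(model, pool)

        out.n_instances += 1
        if (milp_res.status == "optimal" and enum_cost is not None
                and abs(milp_res.total_cost - enum_cost) < 1e-9):
            out.n_milp_matches_enumeration += 1
        if (run.feasible and run.solutions
                and min(s.total_cost for s in run.solutions)
                >= milp_res.total_cost - 1e-9):
            out.n_heuristic_dominated += 1
    return out


@dataclass
class AnalogueResult:
    """One knockout-recovery experiment: sizes of the suggested sets."""

    name: str
    n_removed: int
    pool_size: int
    fgf_smallest: int
    milp_size: int
    fgf_equals_milp_set: bool


def analogue_experiments(
    seed: int, scheme: CostScheme = DEFAULT_SCHEME
) -> list[AnalogueResult]:
    """Chain-model analogues of single-, multi- and yeast-style knockouts.

    Each removes essential biosynthesis steps from a working model (the
    multi-knockout case disturbs several branches at once; the
    yeast-style case removes the four precursor-producing branch
    reactions and uses a 12 mmol/gDW/h glucose-style uptake cap) and asks
    whether heuristic and oracle recover sets of equal size and content.
    """
    results = []
    setups = [
        # name, n_met, biomass_size, uptake_cap, how many branches/steps to cut, decoys
        ("single_knockout", 8, 2, 16.0, 1, 10),
        ("multi_knockout", 14, 4, 16.0, 4, 12),
        ("yeast_style", 12, 4, 12.0, 4, 12),
    ]
    rng = random.Random(seed)
    for name, n_met, bm, cap, n_cut, n_dec in setups:
        inst_seed = rng.randrange(2**31)
        complete = make_chain_model(n_met, bm, inst_seed, uptake_cap=cap)
        branches = sorted(r for r in complete.reactions if r.startswith("B_"))
        others = sorted(
            set(complete.reactions) - set(branches) - {complete.biomass_id}
        )
        # prefer terminal biosynthesis (branch) steps, as in precursor knockouts
        targets = branches[:n_cut]
        if len(targets) < n_cut:
            targets += others[: n_cut - len(targets)]
        incomplete, pool = knockout(complete, set(targets))
        pool = add_decoys(pool, incomplete, n_dec, inst_seed + 1)
        model, pool = prepare(incomplete, pool, scheme=scheme)
        run = fast_gap_filling(model, pool)
        milp_res = milp_gap_fill(model, pool)
        results.append(
            AnalogueResult(
                name=name,
                n_removed=len(targets),
                pool_size=len(pool),
                fgf_smallest=len(run.best.active_set) if run.best else -1,
                milp_size=len(milp_res.active_set) if milp_res.ok else -1,
                fgf_equals_milp_set=(
                    run.best is not None and milp_res.ok
                    and run.best.active_set == milp_res.active_set
                ),
            )
        )
    return results


def heuristic_gap_exhibit(scheme: CostScheme = DEFAULT_SCHEME) -> dict:
    """The over-suggestion phenomenon: the LP search returns one extra
    low-flux reaction over the exact minimum; pruning removes it."""
    incomplete, pool, essential, redundant = make_low_flux_fixture()
    model, pool = prepare(incomplete, pool, scheme=scheme)
    run = fast_gap_filling(model, pool)
    best = run.best
    milp_res = milp_gap_fill(model, pool)
    pruned = prune_low_flux(model, pool, best)
    return {
        "fgf_size": len(best.active_set),
        "milp_size": len(milp_res.active_set),
        "pruned_size": len(pruned.active_set),
        "pruned_verifies": verify_solution(model, pool, pruned),
        "pruned_equals_milp": pruned.active_set == milp_res.active_set,
        "low_flux_ratio": (
            best.candidate_fluxes[redundant] / best.candidate_fluxes[essential]
        ),
    }


def direction_recovery(seed: int, scheme: CostScheme = DEFAULT_SCHEME) -> dict:
    """Knock out a terminal biosynthesis step; offer it back as a
    reversible candidate.  After splitting, only the productive direction
    should be suggested — and nothing else."""
    complete = make_chain_model(6, 2, seed)
    branch = sorted(r for r in complete.reactions if r.startswith("B_"))[0]
    incomplete, pool = knockout(complete, {branch})
    removed = pool.candidates[branch].reaction
    reversible_pool = CandidatePool.create(
        [
            CandidateReaction(
                removed.copy(
                    reversible=True, lower_bound=-removed.upper_bound
                ),
                cost=None,
            )
        ]
    )
    reversible_pool = add_decoys(reversible_pool, incomplete, 8, seed + 1)
    model, pool = prepare(incomplete, reversible_pool, scheme=scheme)
    run = fast_gap_filling(model, pool)
    suggested = sorted(run.best.active_set) if run.best else []
    return {
        "removed": branch,
        "suggested": suggested,
        "recovered_in_correct_direction": suggested == [branch + "_fwd"],
        "pool_size": len(pool),
    }
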