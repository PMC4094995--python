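"""The FastGapFilling driver: binary search on the biomass weight δ.

The LP objective δ·f_b − Σ_{r∈M} c_r f_r rewards biomass flux and
penalizes candidate fluxes.  The search starts with δ = |M| — large
enough to let many candidates be active at once — and halves the bracket
(0, |M|] until its width is ≤ 1.  Whenever a solve yields growth
(f_b above eps_growth) the set of active candidates is recorded and the
upper end of the bracket moves down, pressing the solver to achieve
growth with less candidate flux; otherwise the lower end moves up.
The LP-solve count is therefore at most ⌈log₂|M|⌉ plus the initial probe.

The heuristic does not guarantee the minimum-cost set (see
:mod:`fastgapfill.milp` for the exact oracle); it returns every distinct
growth-positive active set found, smallest first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import DEFAULT_TOLERANCES, Tolerances
from .lp import GapfillLP, build_lp
from .model import CandidatePool, FluxSolution, GapfillSolution, MetabolicModel

log = logging.getLogger(__name__)

INFEASIBLE_ADVICE = (
    "no set of candidate reactions achieves growth; consider reducing the "
    "number of metabolites in the biomass reaction"
)


@dataclass
class GapfillRun:
    """Outcome of a FastGapFilling run.

    ``solutions`` holds the distinct growth-positive active sets, sorted
    by ascending set size, then total cost, then ids.  ``feasible`` is
    False when even the initial probe at δ = |M| found no growth — the
    algorithm's known shortcoming, for which the standing advice is to
    shrink the biomass reaction.
    """

    solutions: list[GapfillSolution] = field(default_factory=list)
    n_lp_solves: int = 0
    feasible: bool = True
    error: bool = False
    message: str = ""

    @property
    def best(self) -> GapfillSolution | None:
        return self.solutions[0] if self.solutions else None


def iteration_count(pool_size: int) -> int:
    """Worst-case LP-solve count for a pool of the given size.

    One initial probe at δ = |M| plus ⌈log₂|M|⌉ bracket halvings (the
    bracket starts at width |M| and the search stops at width ≤ 1).
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return (pool_size - 1).bit_length() + 1  # ceil(log2(n)) + 1


def _record(
    solutions: dict[frozenset, GapfillSolution],
    lp: GapfillLP,
    sol: FluxSolution,
    delta: float,
    pool: CandidatePool,
    eps_active: float,
) -> GapfillSolution:
    active = frozenset(
        rid for rid in lp.candidate_ids if sol.fluxes.get(rid, 0.0) > eps_active
    )
    gs = GapfillSolution(
        delta=delta,
        active_set=active,
        biomass_flux=sol.biomass_flux,
        candidate_fluxes={rid: sol.fluxes[rid] for rid in active},
        total_cost=sum(pool.cost_of(rid) for rid in active),
    )
    prev = solutions.get(active)
    if prev is None or delta < prev.delta:  # keep the smallest-δ occurrence
        solutions[active] = gs
    return gs


def fast_gap_filling(
    model: MetabolicModel,
    pool: CandidatePool,
    eps_growth: float | None = None,
    eps_active: float | None = None,
    tol: Tolerances = DEFAULT_TOLERANCES,
) -> GapfillRun:
    """Search for small candidate sets R ⊆ M restoring growth of N.

    Inputs must be preprocessed (irreversible reactions, environment
    exchanges attached, costs assigned).  Returns a :class:`GapfillRun`;
    its ``solutions`` list is empty when no weighting of the biomass flux
    up to δ = |M| produces growth.
    """
    if len(pool) < 1:
        raise ValueError("candidate pool must contain at least one reaction")
    eps_growth = tol.eps_growth if eps_growth is None else eps_growth
    eps_active = tol.eps_active if eps_active is None else eps_active

    lp = build_lp(model, pool, tol)
    run = GapfillRun()
    found: dict[frozenset, GapfillSolution] = {}
    n = float(len(pool))

    def solve(delta: float) -> FluxSolution | None:
        sol = lp.solve_at(delta)
        run.n_lp_solves += 1
        if sol.solver_status == "error":
            run.error = True
            run.message = f"solver error at delta={delta:g}"
            return None
        grew = sol.optimal and sol.biomass_flux > eps_growth
        if grew:
            gs = _record(found, lp, sol, delta, pool, eps_active)
            n_active = len(gs.active_set)
        else:
            n_active = 0
        log.info(
            "iteration %d: delta=%g status=%s f_b=%g |active|=%d",
            run.n_lp_solves, delta, sol.solver_status,
            sol.biomass_flux if sol.optimal else float("nan"), n_active,
        )
        return sol

    # initial probe at delta = |M|
    sol = solve(n)
    if sol is None:
        return run
    if not (sol.optimal and sol.biomass_flux > eps_growth):
        run.feasible = False
        run.message = INFEASIBLE_ADVICE
        return run

    lo, hi = 0.0, n
    while hi - lo > 1.0:
        delta = (lo + hi) / 2.0
        sol = solve(delta)
        if sol is None:
            break
        if sol.optimal and sol.biomass_flux > eps_growth:
            hi = delta
        else:
            lo = delta

    run.solutions = sorted(
        found.values(),
        key=lambda s: (len(s.active_set), s.total_cost, tuple(sorted(s.active_set))),
    )
    return run
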