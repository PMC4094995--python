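"""Post-hoc verification and pruning of gap-fill solutions.

A suggested set R is *sound* if adding exactly R to the network (with no
flux penalty) lets plain FBA achieve growth.  Candidates carrying only a
relatively tiny flux in the LP optimum may merely top up the biomass
rather than being essential; pruning drops them and keeps the reduction
only if the reduced set still restores growth.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable

from .config import DEFAULT_TOLERANCES, Tolerances
from .lp import maximize_biomass
from .model import (
    CandidatePool,
    FluxSolution,
    GapfillSolution,
    MetabolicModel,
)


def _augmented_fba(
    model: MetabolicModel,
    pool: CandidatePool,
    active_set: Iterable[str],
    tol: Tolerances,
) -> FluxSolution:
    active_set = set(active_set)
    unknown = active_set - pool.ids()
    if unknown:
        raise KeyError(f"active_set ids not in candidate pool: {sorted(unknown)}")
    aug = model.copy()
    for rid in active_set:
        aug.reactions[rid] = pool.candidates[rid].reaction.copy()
    return maximize_biomass(aug, tol)


def verify_solution(
    model: MetabolicModel,
    pool: CandidatePool,
    solution: GapfillSolution | Iterable[str],
    eps_growth: float | None = None,
    tol: Tolerances = DEFAULT_TOLERANCES,
) -> bool:
    """True iff FBA on N ∪ active_set alone achieves growth.

    ``solution`` may be a :class:`GapfillSolution` or a bare iterable of
    candidate ids.  Candidates are added unpenalized with their model
    bounds; growth means biomass flux above ``eps_growth``.
    """
    eps_growth = tol.eps_growth if eps_growth is None else eps_growth
    ids = solution.active_set if isinstance(solution, GapfillSolution) else solution
    sol = _augmented_fba(model, pool, ids, tol)
    return sol.optimal and sol.biomass_flux > eps_growth


def prune_low_flux(
    model: MetabolicModel,
    pool: CandidatePool,
    solution: GapfillSolution,
    flux_ratio_threshold: float = 0.01,
    eps_growth: float | None = None,
    tol: Tolerances = DEFAULT_TOLERANCES,
) -> GapfillSolution:
    """Drop candidates whose flux is small relative to the set's maximum.

    Candidates with flux below ``flux_ratio_threshold`` times the largest
    candidate flux are tentatively removed as a batch; if the reduced set
    still verifies, its fluxes are refreshed from the verifying FBA solve
    and pruning is retried recursively, otherwise the input solution is
    returned unchanged.  The returned solution always verifies (the input
    is assumed verified).
    """
    eps_growth = tol.eps_growth if eps_growth is None else eps_growth
    current = solution
    while current.active_set:
        fluxes = current.candidate_fluxes
        max_flux = max(fluxes[rid] for rid in current.active_set)
        cutoff = flux_ratio_threshold * max_flux
        keep = frozenset(rid for rid in current.active_set if fluxes[rid] >= cutoff)
        if keep == current.active_set:
            break
        sol = _augmented_fba(model, pool, keep, tol)
        if not (sol.optimal and sol.biomass_flux > eps_growth):
            break
        current = replace(
            current,
            active_set=keep,
            biomass_flux=sol.biomass_flux,
            candidate_fluxes={rid: sol.fluxes[rid] for rid in keep},
            total_cost=sum(pool.cost_of(rid) for rid in keep),
        )
    return current
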