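"""Minimum-cost MILP gap-filler: the exact baseline the LP heuristic is
measured against.

One binary inclusion variable y_r per candidate, linked to its flux by
f_r ≤ M_r·y_r with the tightest valid big-M (the candidate's own flux
upper bound); growth is enforced as a hard constraint on the biomass
flux, and the objective minimizes Σ c_r·y_r.  On small pools this finds
the provably cheapest completing set, so it serves as ground truth for
the heuristic's solutions.  Every returned set is re-verified by plain
FBA; if solver tolerances ever admit a set that does not truly restore
growth, a combinatorial cut excluding that set and its subsets (all
equally non-restoring, since adding reactions never removes feasibility)
is added and the program is re-solved.  An alternative soft-biomass formulation — a
per-biomass-metabolite gain (the cost scheme's ``biomass_gain``) traded
against candidate costs, so the solver may sacrifice biomass metabolites
it cannot produce — exists in curation tools; this oracle deliberately
fixes the full biomass instead, matching the problem the LP heuristic
solves.

Solved with HiGHS branch-and-bound via :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix, hstack, identity

from .config import DEFAULT_TOLERANCES, FLUX_CAP, Tolerances
from .lp import build_lp
from .model import CandidatePool, GapfillSolution, MetabolicModel
from .verify import _augmented_fba

#: Biomass-flux floor enforced by the MILP growth constraint.  Kept well
#: above solver feasibility tolerances (big-M linking makes a 1e-6 floor
#: numerically fragile) and far below any realistic growth rate.
DEFAULT_GROWTH_FLOOR = 1e-4


@dataclass
class MilpResult:
    """Outcome of the MILP gap-fill: status is one of
    optimal | feasible_at_limit | timeout | infeasible | error."""

    status: str
    active_set: frozenset[str] = frozenset()
    total_cost: float = 0.0
    biomass_flux: float = 0.0
    candidate_fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status in ("optimal", "feasible_at_limit")

    def as_gapfill_solution(self) -> GapfillSolution:
        return GapfillSolution(
            delta=float("nan"),
            active_set=self.active_set,
            biomass_flux=self.biomass_flux,
            candidate_fluxes=dict(self.candidate_fluxes),
            total_cost=self.total_cost,
        )


def milp_gap_fill(
    model: MetabolicModel,
    pool: CandidatePool,
    time_limit: float = 60.0,
    growth_floor: float = DEFAULT_GROWTH_FLOOR,
    big_m: float | None = None,
    tol: Tolerances = DEFAULT_TOLERANCES,
    max_repairs: int = 10,
) -> MilpResult:
    """Find the minimum-cost candidate set whose addition permits growth.

    Inputs must be preprocessed.  Infeasibility (no candidate subset can
    produce the full biomass) is reported distinctly from hitting the
    time limit with an incumbent.  ``big_m`` overrides the per-candidate
    linking constant (default: each candidate's own upper bound, capped
    at ``FLUX_CAP``).
    """
    lp = build_lp(model, pool, tol)
    n = lp.n_variables
    k = len(lp.candidate_ids)
    if k < 1:
        raise ValueError("candidate pool must contain at least one reaction")
    cand_offset = n - k  # candidates occupy the trailing columns

    # variables: [fluxes (n), inclusion y (k)]
    costs = np.array([pool.cost_of(rid) for rid in lp.candidate_ids])
    c = np.concatenate([np.zeros(n), costs])

    balance = LinearConstraint(
        hstack([lp.A_eq, csr_matrix((lp.n_constraints, k))]), 0.0, 0.0
    )
    # f_r - M_r * y_r <= 0 for candidates
    if big_m is None:
        link_m = np.minimum(lp.bounds[cand_offset:, 1], FLUX_CAP)
    else:
        link_m = np.full(k, float(big_m))
    sel = csr_matrix(
        (np.ones(k), (np.arange(k), cand_offset + np.arange(k))), shape=(k, n)
    )
    linking = LinearConstraint(
        hstack([sel, -identity(k, format="csr").multiply(link_m[:, None])]),
        -np.inf, 0.0,
    )
    growth_row = np.zeros(n + k)
    growth_row[lp.biomass_index] = 1.0
    growth = LinearConstraint(growth_row, growth_floor, np.inf)

    lb = np.concatenate([lp.bounds[:, 0], np.zeros(k)])
    ub = np.concatenate([lp.bounds[:, 1], np.ones(k)])
    integrality = np.concatenate([np.zeros(n), np.ones(k)])

    constraints = [balance, linking, growth]
    for _ in range(max_repairs):
        res = milp(
            c,
            constraints=constraints,
            bounds=Bounds(lb, ub),
            integrality=integrality,
            options={"time_limit": float(time_limit)},
        )
        if res.status == 2:
            return MilpResult(status="infeasible")
        if res.x is None:
            # hit the time limit with no incumbent, or a solver failure
            return MilpResult(status="timeout" if res.status == 1 else "error")
        status = "optimal" if res.status == 0 else "feasible_at_limit"
        y = res.x[n:]
        active = frozenset(
            rid for rid, yi in zip(lp.candidate_ids, y) if yi > 0.5
        )
        # report fluxes from an unpenalized FBA re-solve on N ∪ active
        fba = _augmented_fba(model, pool, active, tol)
        if fba.optimal and fba.biomass_flux > tol.eps_growth:
            return MilpResult(
                status=status,
                active_set=active,
                total_cost=float(sum(pool.cost_of(rid) for rid in active)),
                biomass_flux=fba.biomass_flux,
                candidate_fluxes={
                    rid: fba.fluxes.get(rid, 0.0) for rid in sorted(active)
                },
            )
        # tolerance artifact: the chosen set does not truly restore growth;
        # neither does any of its subsets, so this cut is valid
        cut_row = np.zeros(n + k)
        for j, rid in enumerate(lp.candidate_ids):
            if rid not in active:
                cut_row[n + j] = 1.0
        constraints = constraints + [LinearConstraint(cut_row, 1.0, np.inf)]
    return MilpResult(status="error")
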