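"""Steady-state LP over N ∪ M with the parametric objective δ·f_b − Σ c_r f_r.

The constraint matrix (one mass-balance equality per metabolite, S v = 0)
and the penalty part of the objective are built once; across iterations of
the binary search only the biomass coefficient δ changes, so the same
:class:`GapfillLP` is re-solved cheaply at each δ.

Solved with the HiGHS simplex/IPM backends via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

from .config import DEFAULT_TOLERANCES, Tolerances
from .model import CandidatePool, FluxSolution, MetabolicModel

_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class GapfillLP:
    """A reusable LP: balance equalities, bounds and the objective template.

    Variables are the fluxes of all model reactions (network, exchanges,
    biomass) followed by all candidate reactions.  The objective template
    holds −c_r on candidates and 0 on network reactions; ``solve_at``
    places δ on the biomass variable.
    """

    reaction_ids: list[str]
    candidate_ids: list[str]
    biomass_index: int
    A_eq: csr_matrix
    bounds: np.ndarray  # (n, 2)
    penalty: np.ndarray  # minimize-sense cost vector without the biomass term
    tol: Tolerances = DEFAULT_TOLERANCES

    @property
    def n_variables(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_constraints(self) -> int:
        return self.A_eq.shape[0]

    def solve_at(self, delta: float) -> FluxSolution:
        """Maximize δ·f_b − Σ c_r f_r at the given δ (δ ≥ 0).

        Solver failures are reported through ``solver_status``; this never
        raises for an infeasible or unbounded program.
        """
        if delta < 0:
            raise ValueError("delta must be >= 0")
        c = self.penalty.copy()
        c[self.biomass_index] -= delta  # minimize -(delta * f_b) + sum c_r f_r
        try:
            res = linprog(
                c,
                A_eq=self.A_eq,
                b_eq=np.zeros(self.n_constraints),
                bounds=self.bounds,
                method="highs",
            )
        except Exception:
            return FluxSolution({}, 0.0, 0.0, "error")
        status = _STATUS.get(res.status, "error")
        if status != "optimal" or res.x is None:
            return FluxSolution({}, 0.0, 0.0, status)
        x = np.asarray(res.x, dtype=float)
        x[(x < 0) & (x > -self.tol.eps_balance)] = 0.0
        residual = float(np.max(np.abs(self.A_eq @ x))) if x.size else 0.0
        fluxes = dict(zip(self.reaction_ids, x.tolist()))
        return FluxSolution(
            fluxes=fluxes,
            biomass_flux=float(x[self.biomass_index]),
            objective_value=float(-res.fun),
            solver_status="optimal",
            balance_residual=residual,
        )


def build_lp(
    model: MetabolicModel,
    pool: CandidatePool | None = None,
    tol: Tolerances = DEFAULT_TOLERANCES,
) -> GapfillLP:
    """Assemble the steady-state LP over the model's reactions plus the pool.

    Requires preprocessed inputs: every reaction irreversible with
    lower_bound ≥ 0, environment exchanges attached, and every candidate
    carrying an assigned cost.  Balance rows cover every metabolite
    referenced by the model or by a candidate (candidates may introduce
    their own metabolites, which then must balance like any other).
    """
    model_rxns = list(model.reactions.values())
    cands = list(pool) if pool is not None else []
    for r in model_rxns:
        if r.reversible or r.lower_bound < 0:
            raise ValueError(
                f"reaction {r.id!r} is not LP-ready (reversible or negative "
                f"lower bound); run preprocessing first"
            )
    for c in cands:
        if c.cost is None:
            raise ValueError(f"candidate {c.id!r} has no assigned cost")
        if c.reaction.reversible or c.reaction.lower_bound < 0:
            raise ValueError(f"candidate {c.id!r} is not LP-ready")

    all_rxns = [(r, 0.0) for r in model_rxns] + [(c.reaction, c.cost) for c in cands]
    met_index: dict[str, int] = {}
    for rxn, _ in all_rxns:
        for m in rxn.stoichiometry:
            met_index.setdefault(m, len(met_index))

    rows, cols, data = [], [], []
    n = len(all_rxns)
    bounds = np.zeros((n, 2))
    penalty = np.zeros(n)
    ids = []
    for j, (rxn, cost) in enumerate(all_rxns):
        ids.append(rxn.id)
        bounds[j] = (rxn.lower_bound, rxn.upper_bound)
        penalty[j] = cost
        for m, coeff in rxn.stoichiometry.items():
            rows.append(met_index[m])
            cols.append(j)
            data.append(coeff)
    A_eq = csr_matrix((data, (rows, cols)), shape=(len(met_index), n))
    return GapfillLP(
        reaction_ids=ids,
        candidate_ids=[c.id for c in cands],
        biomass_index=ids.index(model.biomass_id),
        A_eq=A_eq,
        bounds=bounds,
        penalty=penalty,
        tol=tol,
    )


def maximize_biomass(
    model: MetabolicModel, tol: Tolerances = DEFAULT_TOLERANCES
) -> FluxSolution:
    """Plain FBA: maximize the biomass flux alone over the model's reactions."""
    lp = build_lp(model, None, tol)
    return lp.solve_at(1.0)


def export_lp_text(lp: GapfillLP, delta: float) -> str:
    """Render the LP at a given δ in CPLEX-LP text format, for debugging."""
    c = lp.penalty.copy()
    c[lp.biomass_index] -= delta
    lines = ["Maximize", " obj: " + " ".join(
        f"{-coef:+g} {rid}" for rid, coef in zip(lp.reaction_ids, c) if coef != 0.0
    ), "Subject To"]
    A = lp.A_eq.tocoo()
    by_row: dict[int, list[str]] = {}
    for i, j, v in zip(A.row, A.col, A.data):
        by_row.setdefault(int(i), []).append(f"{v:+g} {lp.reaction_ids[j]}")
    for i in sorted(by_row):
        lines.append(f" bal{i}: " + " ".join(by_row[i]) + " = 0")
    lines.append("Bounds")
    for rid, (lb, ub) in zip(lp.reaction_ids, lp.bounds):
        lines.append(f" {lb:g} <= {rid} <= {ub:g}")
    lines.append("End")
    return "\n".join(lines)
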