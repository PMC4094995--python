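"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately bypass the package's LP template: the
free-sign FBA solver models reversible reactions directly with signed
flux bounds, and the brute-force gap-filler enumerates candidate subsets
outright.  They exist to check the package's answers, not to share its
code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from fastgapfill import (
    DEFAULT_SCHEME,
    CandidatePool,
    MetabolicModel,
    add_decoys,
    knockout,
    make_chain_model,
    prepare,
    verify_solution,
)


def free_sign_max_biomass(model: MetabolicModel) -> float:
    """FBA oracle keeping reversible reactions as single signed variables.

    Maximizes the biomass flux subject to S v = 0 with bounds
    [lb, ub] taken literally (lb may be negative).  Used to check that
    reversible-splitting preserves the optimum.
    """
    rxns = list(model.reactions.values())
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    A = np.zeros((len(met_index), len(rxns)))
    bounds = []
    c = np.zeros(len(rxns))
    for j, r in enumerate(rxns):
        for m, coeff in r.stoichiometry.items():
            A[met_index[m], j] = coeff
        lb = r.lower_bound if r.reversible else max(r.lower_bound, 0.0)
        bounds.append((lb, r.upper_bound))
        if r.id == model.biomass_id:
            c[j] = -1.0  # linprog minimizes
    res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds, method="highs")
    assert res.status == 0, f"oracle LP not optimal (status {res.status})"
    return float(-res.fun)


def brute_force_min_cost(
    model: MetabolicModel, pool: CandidatePool
) -> tuple[float | None, frozenset[str] | None]:
    """Exhaustive minimum-cost completion over all candidate subsets.

    Returns ``(min_cost, one minimizing set)`` or ``(None, None)`` when
    no subset restores growth.  Exponential in |M|; only for tiny pools.
    """
    ids = sorted(pool.ids())
    best_cost, best_set = None, None
    for k in range(len(ids) + 1):
        for combo in itertools.combinations(ids, k):
            cost = sum(pool.cost_of(rid) for rid in combo)
            if best_cost is not None and cost >= best_cost:
                continue
            if verify_solution(model, pool, combo):
                best_cost, best_set = cost, frozenset(combo)
    return best_cost, best_set


def make_t1(n_decoys: int = 2, seed: int = 7):
    """The canonical single-knockout instance: a 3-metabolite chain whose
    terminal biomass-precursor step has been removed, plus decoys."""
    complete = make_chain_model(3, 1, 0)
    incomplete, pool = knockout(complete, {"B_M2"})
    pool = add_decoys(pool, incomplete, n_decoys, seed)
    model, pool = prepare(incomplete, pool, scheme=DEFAULT_SCHEME)
    return model, pool, "B_M2"


@pytest.fixture
def t1():
    return make_t1()


@pytest.fixture
def t1_complete():
    model, _ = prepare(make_chain_model(3, 1, 0))
    return model
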