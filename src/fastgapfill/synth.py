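"""Deterministic synthetic gap-filling instances.

The generator emulates the benchmark protocol used to evaluate
gap-filling methods: start from a working model (every biomass precursor
reachable from the nutrient), remove reactions until growth is
impossible, and offer a candidate pool containing the removed reactions
diluted among many decoys (standing in for a large reaction database).

Topology: a linear backbone from a single capped nutrient, with one
branch reaction per biomass precursor attached to backbone metabolites;
every reaction is essential because the biomass consumes all precursors
and the branches span the full backbone.  Decoy reactions each touch a
fresh dead-end metabolite, so steady state forces their flux to zero and
they can never substitute for a removed reaction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .config import DEFAULT_TOLERANCES, Tolerances
from .lp import maximize_biomass
from .model import (
    CandidatePool,
    CandidateReaction,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from .preprocess import attach_environment
from .verify import verify_solution

#: Default nutrient uptake cap for generated models, mmol/gDW/h.
DEFAULT_UPTAKE_CAP = 10.0

#: Biomass demand per precursor (mmol/gDW).  Kept small, as in real
#: biomass equations, so the per-unit-biomass cost of any candidate route
#: stays well below the initial search weight delta = |M|.
BIOMASS_COEFF = 0.01

_DECOY_STATUSES = ("in_range", "unknown", "out_of_range")


def make_chain_model(
    n_metabolites: int,
    biomass_size: int,
    seed: int,
    uptake_cap: float = DEFAULT_UPTAKE_CAP,
    tol: Tolerances = DEFAULT_TOLERANCES,
) -> MetabolicModel:
    """A growth-positive branched-pathway model, deterministic per seed.

    Metabolites ``M0..M{n-1}``: the first ``n - biomass_size`` form the
    backbone fed by nutrient ``M0`` (reactions ``R1..``), the rest are
    biomass precursors produced by branch reactions ``B_<precursor>``
    attached to seeded-random backbone positions (the last backbone
    metabolite always carries a branch, keeping every backbone step
    essential).  Growth is asserted at construction.
    """
    if not (n_metabolites >= biomass_size >= 1):
        raise ValueError("require n_metabolites >= biomass_size >= 1")
    rng = random.Random(seed)
    met_ids = [f"M{i}" for i in range(n_metabolites)]
    n_chain = n_metabolites - biomass_size
    if n_chain == 0:
        # degenerate: the nutrient itself is the first precursor
        chain = [met_ids[0]]
        precursors = met_ids[1:] if n_metabolites > 1 else []
        biomass_mets = list(met_ids)
    else:
        chain = met_ids[:n_chain]
        precursors = met_ids[n_chain:]
        biomass_mets = list(precursors)

    reactions = []
    for i in range(len(chain) - 1):
        reactions.append(
            Reaction(
                id=f"R{i + 1}",
                stoichiometry={chain[i]: -1.0, chain[i + 1]: 1.0},
                kind="enzymatic",
                taxonomic_status="in_range",
            )
        )
    # branch attachment points; force the last backbone metabolite to be used
    attach = [rng.randrange(len(chain)) for _ in precursors]
    if precursors:
        attach[rng.randrange(len(precursors))] = len(chain) - 1
    for p, a in zip(precursors, attach):
        reactions.append(
            Reaction(
                id=f"B_{p}",
                stoichiometry={chain[a]: -1.0, p: 1.0},
                kind="enzymatic",
                taxonomic_status="in_range",
            )
        )
    if not biomass_mets:
        biomass_mets = [chain[-1]]
    reactions.append(
        Reaction(
            id="BIOMASS",
            stoichiometry={m: -BIOMASS_COEFF for m in biomass_mets},
            kind="biomass",
            taxonomic_status="not_applicable",
        )
    )
    model = MetabolicModel.create(
        metabolites=(Metabolite(m) for m in met_ids),
        reactions=reactions,
        biomass_id="BIOMASS",
        nutrients={met_ids[0]: uptake_cap},
        secretions=(),
    )
    grown = maximize_biomass(attach_environment(model), tol)
    assert grown.optimal and grown.biomass_flux > tol.eps_growth, (
        "construction bug: generated model does not grow"
    )
    return model


def knockout(
    model: MetabolicModel,
    reaction_ids: set[str] | frozenset[str],
    tol: Tolerances = DEFAULT_TOLERANCES,
) -> tuple[MetabolicModel, CandidatePool]:
    """Remove reactions so growth becomes impossible; pool = the removals.

    The removed reactions (with unset costs, for later default costing)
    form the initial candidate pool.  Raises if any id is unknown, if the
    biomass reaction is targeted, or if the knockout fails to prohibit
    growth (a parallel route remains).
    """
    reaction_ids = set(reaction_ids)
    unknown = reaction_ids - set(model.reactions)
    if unknown:
        raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
    if model.biomass_id in reaction_ids:
        raise ValueError("cannot knock out the biomass reaction")
    incomplete = model.copy()
    removed = [incomplete.reactions.pop(rid) for rid in sorted(reaction_ids)]
    grown = maximize_biomass(attach_environment(incomplete), tol)
    if grown.optimal and grown.biomass_flux > tol.eps_growth:
        raise ValueError(
            f"growth not prohibited: knockout leaves biomass flux "
            f"{grown.biomass_flux:g}"
        )
    pool = CandidatePool.create(
        CandidateReaction(reaction=r.copy(), cost=None) for r in removed
    )
    return incomplete, pool


def add_decoys(
    pool: CandidatePool,
    model: MetabolicModel,
    n_decoys: int,
    seed: int,
) -> CandidatePool:
    """Dilute the pool with seeded-random flux-incapable decoy reactions.

    Each decoy links one or two model metabolites to a fresh dead-end
    metabolite (``DEC_MET_<k>``) with coefficients from {1, 2} and a
    random kind / taxonomic status.  Because the dead-end metabolite has
    no other producer or consumer, mass balance pins every decoy's flux
    to zero, so decoys are never required (nor usable) for growth.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    if n_decoys == 0:
        return pool
    rng = random.Random(seed)
    met_ids = sorted(model.metabolites)
    taken = pool.ids() | set(model.reactions)
    out = list(pool)
    for k in range(n_decoys):
        dead_end = f"DEC_MET_{k}"
        n_subs = rng.choice((1, 2))
        subs = rng.sample(met_ids, min(n_subs, len(met_ids)))
        stoich = {m: -float(rng.choice((1, 2))) for m in subs}
        if rng.random() < 0.5:
            stoich[dead_end] = float(rng.choice((1, 2)))  # produces the dead end
        else:
            stoich = {m: -c for m, c in stoich.items()}
            stoich[dead_end] = -float(rng.choice((1, 2)))  # consumes it (no source)
        kind = "spontaneous" if rng.random() < 0.2 else "enzymatic"
        rid = f"DEC_{k}"
        if rid in taken:
            raise ValueError(f"decoy id {rid!r} collides with an existing id")
        out.append(
            CandidateReaction(
                reaction=Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    kind=kind,
                    taxonomic_status=(
                        "not_applicable" if kind == "spontaneous"
                        else rng.choice(_DECOY_STATUSES)
                    ),
                ),
                cost=None,
            )
        )
        taken.add(rid)
    return CandidatePool.create(out)


def make_low_flux_fixture() -> tuple[MetabolicModel, CandidatePool, str, str]:
    """An instance where the LP heuristic over-suggests a low-flux candidate.

    The model grows through a single backbone (nutrient A → B → C →
    biomass) whose first step has been removed; candidate ``RA`` restores
    it.  A second candidate ``RE`` (B + X → 2 C, with side substrate X
    capped at a trickle) slightly boosts biomass whenever it may run, so
    the LP activates it alongside ``RA`` at a tiny flux — but it is not
    essential, and the exact minimum-cost set is {RA} alone.  Returns
    ``(incomplete_model, pool, essential_id, redundant_id)``.
    """
    model = MetabolicModel.create(
        metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C"), Metabolite("X")],
        reactions=[
            Reaction(id="R_AB", stoichiometry={"A": -1.0, "B": 1.0},
                     taxonomic_status="in_range"),
            Reaction(id="R_BC", stoichiometry={"B": -1.0, "C": 1.0},
                     taxonomic_status="in_range"),
            Reaction(
                id="BIOMASS", stoichiometry={"C": -BIOMASS_COEFF}, kind="biomass",
                taxonomic_status="not_applicable",
            ),
        ],
        biomass_id="BIOMASS",
        nutrients={"A": 10.0, "X": 0.001},
        secretions=(),
    )
    incomplete, pool = knockout(model, {"R_AB"})
    candidates = list(pool) + [
        CandidateReaction(
            reaction=Reaction(
                id="RE",
                stoichiometry={"B": -1.0, "X": -1.0, "C": 2.0},
                kind="spontaneous",
                taxonomic_status="not_applicable",
            ),
            cost=None,
        )
    ]
    return incomplete, CandidatePool.create(candidates), "R_AB", "RE"


def make_multi_solution_fixture(
    n_decoys: int = 29, seed: int = 0
) -> tuple[MetabolicModel, CandidatePool]:
    """An instance whose search records several distinct solution sets.

    The biomass precursor Z has no route in the model.  Candidate ``RC2``
    (spontaneous, cheap) can make Z but its flux is capped at a trickle;
    candidate ``RC1`` (enzymatic, pricier) is uncapped.  At high biomass
    weight delta both are worth running, at low delta only the cheap one,
    so the binary search returns both ``{RC1, RC2}`` and the smaller
    ``{RC2}``.  Decoys enlarge the pool so the search explores weights
    across the transition.  Biomass coefficients are 1 here so the
    activation thresholds fall inside the searched delta range.
    """
    model = MetabolicModel.create(
        metabolites=[Metabolite("A"), Metabolite("Z")],
        reactions=[
            Reaction(
                id="BIOMASS", stoichiometry={"Z": -1.0}, kind="biomass",
                taxonomic_status="not_applicable",
            )
        ],
        biomass_id="BIOMASS",
        nutrients={"A": 10.0},
        secretions=(),
    )
    pool = CandidatePool.create(
        [
            CandidateReaction(
                Reaction(id="RC1", stoichiometry={"A": -1.0, "Z": 1.0},
                         kind="enzymatic", taxonomic_status="in_range")
            ),
            CandidateReaction(
                Reaction(id="RC2", stoichiometry={"A": -1.0, "Z": 1.0},
                         upper_bound=2.0, kind="spontaneous",
                         taxonomic_status="not_applicable")
            ),
        ]
    )
    return model, add_decoys(pool, model, n_decoys, seed)


@dataclass(frozen=True)
class InstanceSpec:
    """Parameters of one benchmark instance."""

    n_metabolites: int
    biomass_size: int
    n_knockouts: int
    n_decoys: int
    seed: int


def benchmark_instances(seed: int, n_instances: int = 50) -> list[InstanceSpec]:
    """A reproducible roster of instances spanning 1–14 knockouts and
    pool sizes from a handful up to several thousand candidates."""
    rng = random.Random(seed)
    specs = []
    # a few large-pool instances, the rest small/medium
    decoy_plan = [5000, 2000, 1000] + [0] * (n_instances - 3)
    for i in range(n_instances):
        n_k = 1 + (i % 14)
        biomass_size = rng.randint(1, 4)
        n_met = max(biomass_size + n_k + 2, rng.randint(8, 24))
        n_dec = decoy_plan[i] if i < 3 else rng.choice((2, 5, 10, 25, 50, 150, 300))
        specs.append(
            InstanceSpec(
                n_metabolites=n_met,
                biomass_size=biomass_size,
                n_knockouts=n_k,
                n_decoys=n_dec,
                seed=rng.randrange(2**31),
            )
        )
    return specs


def realize_instance(
    spec: InstanceSpec, tol: Tolerances = DEFAULT_TOLERANCES
) -> tuple[MetabolicModel, CandidatePool, frozenset[str]]:
    """Build (incomplete model, pool with decoys, removed-reaction ids).

    The removed set is verified to restore growth before returning, so
    every instance is a valid, completable gap-filling problem.
    """
    rng = random.Random(spec.seed)
    model = make_chain_model(spec.n_metabolites, spec.biomass_size, spec.seed, tol=tol)
    knockable = sorted(set(model.reactions) - {model.biomass_id})
    n_k = min(spec.n_knockouts, len(knockable))
    targets = set(rng.sample(knockable, n_k))
    incomplete, pool = knockout(model, targets, tol)
    pool = add_decoys(pool, incomplete, spec.n_decoys, spec.seed + 1)
    removed = frozenset(targets)
    assert verify_solution(attach_environment(incomplete), pool, removed, tol=tol), (
        "construction bug: removed set does not restore growth"
    )
    return incomplete, pool, removed
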