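"""Domain types for metabolic networks, candidate pools and solutions.

A :class:`MetabolicModel` is a set of metabolites, a set of reactions
(the network ``N``), one designated biomass reaction, and a growth
environment (nutrients with uptake caps, secretions).  A
:class:`CandidatePool` is the set ``M`` of reactions considered for
addition, each carrying a non-negative cost ``c_r``.

The native on-disk representation is a small JSON dialect::

    {
      "metabolites": [{"id": ..., "name": ..., "compartment": ...}, ...],
      "reactions":   [{"id": ..., "stoichiometry": {met: coeff, ...},
                       "reversible": bool, "lower_bound": f, "upper_bound": f,
                       "kind": ..., "taxonomic_status": ...}, ...],
      "biomass": "<reaction id>",
      "nutrients": [{"id": ..., "max_uptake": f-or-null}, ...],
      "secretions": ["<metabolite id>", ...]
    }

A pool file is ``{"candidates": [{...reaction fields..., "cost": f-or-null},
...]}``; a null cost requests default cost assignment (see
:mod:`fastgapfill.costs`).

Stoichiometric coefficients are signed doubles: negative = consumed,
positive = produced.  Comparisons downstream use the LP tolerance
``eps_balance``; exact rational arithmetic is deliberately not used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .config import DEFAULT_UPPER_BOUND

REACTION_KINDS = ("spontaneous", "enzymatic", "exchange", "biomass")
TAXONOMIC_STATUSES = ("in_range", "unknown", "out_of_range", "not_applicable")


@dataclass(frozen=True)
class Metabolite:
    """A compound; ``compartment`` is carried but not interpreted."""

    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A reaction with signed stoichiometry and flux bounds (mmol/gDW/h).

    ``kind`` distinguishes spontaneous (non-enzymatic), enzymatic,
    boundary exchange and biomass pseudo-reactions; ``taxonomic_status``
    records whether the reaction is known in the organism's taxonomic
    range (used for default cost assignment).
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER_BOUND
    kind: str = "enzymatic"
    taxonomic_status: str = "not_applicable"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"unknown reaction kind {self.kind!r}")
        if self.taxonomic_status not in TAXONOMIC_STATUSES:
            raise ValueError(f"unknown taxonomic_status {self.taxonomic_status!r}")

    def copy(self, **changes) -> "Reaction":
        r = replace(self, **changes)
        if "stoichiometry" not in changes:
            r.stoichiometry = dict(self.stoichiometry)
        return r

    @property
    def consumed(self) -> set[str]:
        return {m for m, c in self.stoichiometry.items() if c < 0}

    @property
    def produced(self) -> set[str]:
        return {m for m, c in self.stoichiometry.items() if c > 0}


def _unique_by_id(items: Iterable, what: str) -> dict:
    out: dict[str, object] = {}
    for item in items:
        if item.id in out:
            raise ValueError(f"duplicate {what} id {item.id!r}")
        out[item.id] = item
    return out


@dataclass
class MetabolicModel:
    """The network ``N`` with its biomass reaction and growth environment.

    ``nutrients`` maps a metabolite id to its maximum uptake flux; a value
    of ``None`` means uncapped (a large finite bound is substituted when
    the LP is built).
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_id: str
    nutrients: dict[str, float | None] = field(default_factory=dict)
    secretions: set[str] = field(default_factory=set)

    @classmethod
    def create(
        cls,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_id: str,
        nutrients: Mapping[str, float | None] | None = None,
        secretions: Iterable[str] = (),
    ) -> "MetabolicModel":
        return cls(
            metabolites=_unique_by_id(metabolites, "metabolite"),
            reactions=_unique_by_id(reactions, "reaction"),
            biomass_id=biomass_id,
            nutrients=dict(nutrients or {}),
            secretions=set(secretions),
        )

    @property
    def biomass(self) -> Reaction:
        return self.reactions[self.biomass_id]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            biomass_id=self.biomass_id,
            nutrients=dict(self.nutrients),
            secretions=set(self.secretions),
        )


@dataclass
class CandidateReaction:
    """A pool member: a reaction plus its cost ``c_r`` (None = unassigned)."""

    reaction: Reaction
    cost: float | None = None

    def __post_init__(self) -> None:
        if self.cost is not None and self.cost < 0:
            raise ValueError(f"candidate {self.reaction.id!r}: cost must be >= 0")

    @property
    def id(self) -> str:
        return self.reaction.id


@dataclass
class CandidatePool:
    """The candidate set ``M``."""

    candidates: dict[str, CandidateReaction]

    @classmethod
    def create(cls, candidates: Iterable[CandidateReaction]) -> "CandidatePool":
        return cls(candidates=_unique_by_id(candidates, "candidate"))

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates.values())

    def ids(self) -> set[str]:
        return set(self.candidates)

    def cost_of(self, rid: str) -> float:
        c = self.candidates[rid].cost
        if c is None:
            raise ValueError(f"candidate {rid!r} has no assigned cost")
        return c


@dataclass
class FluxSolution:
    """An LP optimum: per-reaction fluxes ``f_r`` and the biomass flux ``f_b``."""

    fluxes: dict[str, float]
    biomass_flux: float
    objective_value: float
    solver_status: str  # optimal | infeasible | unbounded | error
    balance_residual: float = 0.0

    @property
    def optimal(self) -> bool:
        return self.solver_status == "optimal"


@dataclass
class GapfillSolution:
    """A growth-positive active set ``R`` recorded at some weight delta."""

    delta: float
    active_set: frozenset[str]
    biomass_flux: float
    candidate_fluxes: dict[str, float]
    total_cost: float

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "active_set": sorted(self.active_set),
            "biomass_flux": self.biomass_flux,
            "candidate_fluxes": {k: self.candidate_fluxes[k] for k in sorted(self.candidate_fluxes)},
            "total_cost": self.total_cost,
        }


# ---------------------------------------------------------------------------
# Validation


def validate_model(model: MetabolicModel) -> list[str]:
    """Check structural invariants; returns one diagnostic string per violation.

    An empty list means the model is well-formed.  Diagnostics, not
    exceptions: the caller decides whether to proceed.
    """
    diags: list[str] = []
    mets = set(model.metabolites)
    for rid, rxn in model.reactions.items():
        dangling = set(rxn.stoichiometry) - mets
        for m in sorted(dangling):
            diags.append(f"reaction {rid!r} references unknown metabolite {m!r}")
        if not rxn.stoichiometry and rxn.kind != "exchange":
            diags.append(f"reaction {rid!r} has empty stoichiometry")
        if not rxn.reversible and rxn.lower_bound < 0:
            diags.append(f"irreversible reaction {rid!r} has negative lower bound")
        if rxn.lower_bound > rxn.upper_bound:
            diags.append(f"reaction {rid!r} has lower_bound > upper_bound")
    if model.biomass_id not in model.reactions:
        diags.append(f"biomass reaction {model.biomass_id!r} not found")
    else:
        if not model.biomass.consumed:
            diags.append("empty biomass: biomass reaction consumes no metabolite")
    for n in sorted(set(model.nutrients) - mets):
        diags.append(f"nutrient {n!r} is not a model metabolite")
    for s in sorted(model.secretions - mets):
        diags.append(f"secretion {s!r} is not a model metabolite")
    return diags


def validate_pool(model: MetabolicModel, pool: CandidatePool) -> list[str]:
    """Pool-level diagnostics; id collisions with the model are errors upstream.

    Candidates are allowed to duplicate the stoichiometry of an existing
    model reaction under a different id; this is flagged as a note so a
    curator can spot it.
    """
    diags: list[str] = []
    collisions = pool.ids() & set(model.reactions)
    for rid in sorted(collisions):
        diags.append(f"candidate id {rid!r} collides with a model reaction id")
    signatures = {
        rid: tuple(sorted(r.stoichiometry.items())) for rid, r in model.reactions.items()
    }
    by_sig: dict[tuple, str] = {sig: rid for rid, sig in signatures.items()}
    for cand in pool:
        sig = tuple(sorted(cand.reaction.stoichiometry.items()))
        if sig in by_sig:
            diags.append(
                f"note: candidate {cand.id!r} duplicates stoichiometry of "
                f"model reaction {by_sig[sig]!r}"
            )
    return diags


# ---------------------------------------------------------------------------
# JSON dialect (de)serialization


def _reaction_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "stoichiometry": dict(r.stoichiometry),
        "reversible": r.reversible,
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "kind": r.kind,
        "taxonomic_status": r.taxonomic_status,
    }


def _reaction_from_dict(d: Mapping) -> Reaction:
    return Reaction(
        id=d["id"],
        stoichiometry={str(k): float(v) for k, v in d["stoichiometry"].items()},
        reversible=bool(d.get("reversible", False)),
        lower_bound=float(d.get("lower_bound", 0.0)),
        upper_bound=float(d.get("upper_bound", DEFAULT_UPPER_BOUND)),
        kind=d.get("kind", "enzymatic"),
        taxonomic_status=d.get("taxonomic_status", "not_applicable"),
    )


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [_reaction_to_dict(r) for r in model.reactions.values()],
        "biomass": model.biomass_id,
        "nutrients": [
            {"id": n, "max_uptake": cap} for n, cap in model.nutrients.items()
        ],
        "secretions": sorted(model.secretions),
    }


def model_from_dict(d: Mapping) -> MetabolicModel:
    model = MetabolicModel.create(
        metabolites=(
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", "c"))
            for m in d["metabolites"]
        ),
        reactions=(_reaction_from_dict(r) for r in d["reactions"]),
        biomass_id=d["biomass"],
        nutrients={
            n["id"]: (None if n.get("max_uptake") is None else float(n["max_uptake"]))
            for n in d.get("nutrients", [])
        },
        secretions=d.get("secretions", []),
    )
    # unknown nutrient/secretion ids are a load-time error
    unknown = (set(model.nutrients) | model.secretions) - set(model.metabolites)
    if unknown:
        raise ValueError(f"unknown metabolite ids in environment: {sorted(unknown)}")
    return model


def pool_to_dict(pool: CandidatePool) -> dict:
    return {
        "candidates": [
            {**_reaction_to_dict(c.reaction), "cost": c.cost} for c in pool
        ]
    }


def pool_from_dict(d: Mapping) -> CandidatePool:
    return CandidatePool.create(
        CandidateReaction(
            reaction=_reaction_from_dict(c),
            cost=None if c.get("cost") is None else float(c["cost"]),
        )
        for c in d["candidates"]
    )


def load_model(path: str | Path) -> MetabolicModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def save_model(model: MetabolicModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_pool(path: str | Path, model: MetabolicModel | None = None) -> CandidatePool:
    pool = pool_from_dict(json.loads(Path(path).read_text()))
    if model is not None:
        collisions = pool.ids() & set(model.reactions)
        if collisions:
            raise ValueError(
                f"candidate ids collide with model reaction ids: {sorted(collisions)}"
            )
    return pool


def save_pool(pool: CandidatePool, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(pool_to_dict(pool), fh, indent=1)
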