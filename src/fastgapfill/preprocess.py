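"""Preprocessing: split reversible reactions, instantiate generic reactions,
attach exchange reactions for the growth environment.

After preprocessing every reaction is irreversible with a non-negative
lower bound, so all flux variables in the LP are non-negative — the
standard transformation for flux-balance models.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .config import FLUX_CAP
from .costs import CostScheme, assign_costs
from .model import (
    CandidatePool,
    CandidateReaction,
    MetabolicModel,
    Metabolite,
    Reaction,
    validate_model,
)

log = logging.getLogger(__name__)

FWD_SUFFIX = "_fwd"
REV_SUFFIX = "_rev"


@dataclass
class ClassMap:
    """Membership of compound classes, for instantiating generic reactions.

    ``members`` maps a class id to the concrete metabolite ids that may
    replace it.  Classes listed together in a ``linked`` group are
    substituted in lockstep (the i-th member of each), which expresses a
    chemically coherent pairing such as a compound class and its
    phosphorylated counterpart; unlinked classes combine by Cartesian
    product.
    """

    members: dict[str, list[str]]
    linked: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for group in self.linked:
            sizes = {len(self.members[c]) for c in group}
            if len(sizes) > 1:
                raise ValueError(f"linked classes {group} have unequal member counts")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassMap":
        if "members" in d:
            return cls(
                members={k: list(v) for k, v in d["members"].items()},
                linked=[tuple(g) for g in d.get("linked", [])],
            )
        return cls(members={k: list(v) for k, v in d.items()})

    @classmethod
    def load(cls, path: str | Path) -> "ClassMap":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def check_against(self, model: MetabolicModel) -> None:
        known = set(model.metabolites)
        for cid, mem in self.members.items():
            missing = set(mem) - known
            if missing:
                raise ValueError(
                    f"class {cid!r} members not in model: {sorted(missing)}"
                )


def split_reversible(reactions: Iterable[Reaction]) -> list[Reaction]:
    """Replace each reversible reaction with two opposed irreversible ones.

    ``r`` with bounds ``[lb, ub]`` becomes ``r_fwd`` (same stoichiometry,
    bounds ``[0, ub]``) and ``r_rev`` (negated stoichiometry, bounds
    ``[0, -lb]`` when ``lb < 0``, else ``[0, ub]``).  Irreversible
    reactions pass through unchanged.  Derived ids use fixed suffixes;
    a collision with an existing id is an error.
    """
    reactions = list(reactions)
    existing = {r.id for r in reactions}
    out: list[Reaction] = []
    for r in reactions:
        if not r.reversible:
            out.append(r)
            continue
        fwd_id, rev_id = r.id + FWD_SUFFIX, r.id + REV_SUFFIX
        for did in (fwd_id, rev_id):
            if did in existing:
                raise ValueError(
                    f"split of reversible {r.id!r} derives id {did!r}, "
                    f"which collides with an existing reaction id"
                )
        rev_ub = -r.lower_bound if r.lower_bound < 0 else r.upper_bound
        out.append(
            r.copy(id=fwd_id, reversible=False, lower_bound=0.0, upper_bound=r.upper_bound)
        )
        out.append(
            r.copy(
                id=rev_id,
                stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                reversible=False,
                lower_bound=0.0,
                upper_bound=rev_ub,
            )
        )
        existing.update((fwd_id, rev_id))
    return out


def split_reversible_pool(pool: CandidatePool) -> CandidatePool:
    """Split reversible candidates; each direction inherits the full parent cost."""
    out: list[CandidateReaction] = []
    for cand in pool:
        for r in split_reversible([cand.reaction]):
            out.append(CandidateReaction(reaction=r, cost=cand.cost))
    return CandidatePool.create(out)


def instantiate_generic(reaction: Reaction, classes: ClassMap) -> list[Reaction]:
    """Expand a reaction over compound classes into concrete reactions.

    Each class id appearing in the stoichiometry is replaced by each of
    its members; distinct classes combine by Cartesian product, except
    classes in the same ``linked`` group, which are substituted
    positionally together.  A reaction with no class references is
    returned unchanged (singleton).  A referenced class with no members
    makes the reaction uninstantiable: it is dropped with a warning.
    """
    class_ids = [m for m in reaction.stoichiometry if m in classes.members]
    if not class_ids:
        return [reaction]
    for cid in class_ids:
        if not classes.members[cid]:
            log.warning(
                "dropping reaction %r: class %r has no members", reaction.id, cid
            )
            return []

    # group class ids: linked groups move together, the rest are singletons
    grouped: list[tuple[str, ...]] = []
    seen: set[str] = set()
    for cid in class_ids:
        if cid in seen:
            continue
        group = next(
            (g for g in classes.linked if cid in g), (cid,)
        )
        group = tuple(c for c in group if c in class_ids)
        grouped.append(group)
        seen.update(group)

    choices: list[Sequence[int]] = [
        range(len(classes.members[g[0]])) for g in grouped
    ]
    out: list[Reaction] = []
    for combo in itertools.product(*choices):
        subst = {
            cid: classes.members[cid][idx]
            for group, idx in zip(grouped, combo)
            for cid in group
        }
        stoich: dict[str, float] = {}
        for m, c in reaction.stoichiometry.items():
            stoich[subst.get(m, m)] = stoich.get(subst.get(m, m), 0.0) + c
        new_id = reaction.id + "__" + "__".join(subst[c] for c in class_ids)
        out.append(reaction.copy(id=new_id, stoichiometry=stoich))
    return out


def instantiate_pool(pool: CandidatePool, classes: ClassMap) -> CandidatePool:
    out: list[CandidateReaction] = []
    for cand in pool:
        for r in instantiate_generic(cand.reaction, classes):
            out.append(CandidateReaction(reaction=r, cost=cand.cost))
    return CandidatePool.create(out)


def attach_environment(model: MetabolicModel) -> MetabolicModel:
    """Add boundary exchange reactions realizing the growth environment.

    Each nutrient ``n`` gets an uptake pseudo-reaction ``EX_<n>_in``
    (nothing -> n) bounded by its uptake cap (``FLUX_CAP`` when uncapped);
    each secretion ``s`` gets an export ``EX_<s>_out`` (s -> nothing)
    bounded by ``FLUX_CAP``.  Idempotent: exchanges already present are
    left alone.
    """
    mets = set(model.metabolites)
    unknown = (set(model.nutrients) | model.secretions) - mets
    if unknown:
        raise ValueError(f"environment references unknown metabolites: {sorted(unknown)}")
    out = model.copy()
    for n, cap in model.nutrients.items():
        rid = f"EX_{n}_in"
        if rid in out.reactions:
            continue
        out.reactions[rid] = Reaction(
            id=rid,
            stoichiometry={n: 1.0},
            upper_bound=FLUX_CAP if cap is None else float(cap),
            kind="exchange",
            taxonomic_status="not_applicable",
        )
    for s in model.secretions:
        rid = f"EX_{s}_out"
        if rid in out.reactions:
            continue
        out.reactions[rid] = Reaction(
            id=rid,
            stoichiometry={s: -1.0},
            upper_bound=FLUX_CAP,
            kind="exchange",
            taxonomic_status="not_applicable",
        )
    return out


def prepare(
    model: MetabolicModel,
    pool: CandidatePool | None = None,
    classes: ClassMap | None = None,
    scheme: CostScheme | None = None,
) -> tuple[MetabolicModel, CandidatePool | None]:
    """Full pipeline from a raw model + pool to LP-ready form.

    Validates, instantiates generic candidates against ``classes``,
    splits reversible reactions in both network and pool, attaches the
    growth environment, and assigns default costs under ``scheme`` to
    candidates whose cost is unset.
    """
    diags = validate_model(model)
    errors = [d for d in diags if not d.startswith("note:")]
    if errors:
        raise ValueError("invalid model: " + "; ".join(errors))
    m = model.copy()
    m.reactions = {r.id: r for r in split_reversible(m.reactions.values())}
    m = attach_environment(m)
    p = pool
    if p is not None:
        if classes is not None:
            p = instantiate_pool(p, classes)
        p = split_reversible_pool(p)
        if scheme is not None:
            p = assign_costs(p, scheme)
        collisions = p.ids() & set(m.reactions)
        if collisions:
            raise ValueError(
                f"candidate ids collide with model reaction ids: {sorted(collisions)}"
            )
    return m, p
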