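"""Default candidate costs by reaction kind and taxonomic status.

The weighting expresses how plausible a candidate is for the organism:
a spontaneous (non-enzymatic) reaction can occur anywhere and is cheapest;
an enzymatic reaction known inside the organism's taxonomic range is
preferred over one of unknown range, which is preferred over one known
only outside the range.  Only the relative values matter.  The biomass
gain is used by the soft-biomass MILP variant, not by the LP heuristic
(there the biomass weight is the searched parameter delta).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

from .model import CandidatePool, CandidateReaction


@dataclass(frozen=True)
class CostScheme:
    spontaneous_cost: float = 1.0
    in_range_cost: float = 5.0
    unknown_range_cost: float = 10.0
    out_of_range_cost: float = 15.0
    biomass_gain: float = 500.0

    def __post_init__(self) -> None:
        vals = (
            self.spontaneous_cost,
            self.in_range_cost,
            self.unknown_range_cost,
            self.out_of_range_cost,
        )
        if any(v < 0 for v in vals) or self.biomass_gain <= 0:
            raise ValueError("costs must be >= 0 and biomass_gain > 0")
        if not (vals[0] <= vals[1] <= vals[2] <= vals[3]):
            raise ValueError(
                "cost ordering violated: require spontaneous <= in_range "
                "<= unknown_range <= out_of_range"
            )

    @property
    def gain_cost_ratio(self) -> float:
        """Ratio of the biomass gain to the in-taxonomic-range reaction cost."""
        return self.biomass_gain / self.in_range_cost

    @classmethod
    def from_dict(cls, d: Mapping) -> "CostScheme":
        return replace(DEFAULT_SCHEME, **{k: float(v) for k, v in d.items()})

    @classmethod
    def load(cls, path: str | Path) -> "CostScheme":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "spontaneous_cost": self.spontaneous_cost,
            "in_range_cost": self.in_range_cost,
            "unknown_range_cost": self.unknown_range_cost,
            "out_of_range_cost": self.out_of_range_cost,
            "biomass_gain": self.biomass_gain,
        }


DEFAULT_SCHEME = CostScheme()

_STATUS_FIELD = {
    "in_range": "in_range_cost",
    "unknown": "unknown_range_cost",
    "out_of_range": "out_of_range_cost",
}


def assign_costs(pool: CandidatePool, scheme: CostScheme = DEFAULT_SCHEME) -> CandidatePool:
    """Fill in default costs for candidates whose cost is unset.

    Explicit costs are kept.  Spontaneous reactions get the spontaneous
    cost regardless of taxonomic status; enzymatic reactions get the cost
    matching their taxonomic status, which must therefore be set.
    Idempotent: a second application changes nothing.
    """
    out: list[CandidateReaction] = []
    for cand in pool:
        if cand.cost is not None:
            out.append(cand)
            continue
        r = cand.reaction
        if r.kind == "spontaneous":
            cost = scheme.spontaneous_cost
        elif r.kind == "enzymatic":
            field_name = _STATUS_FIELD.get(r.taxonomic_status)
            if field_name is None:
                raise ValueError(
                    f"enzymatic candidate {r.id!r} needs a taxonomic_status "
                    f"(in_range/unknown/out_of_range) for default costing"
                )
            cost = getattr(scheme, field_name)
        else:
            raise ValueError(
                f"candidate {r.id!r} of kind {r.kind!r} needs an explicit cost"
            )
        out.append(CandidateReaction(reaction=r, cost=cost))
    return CandidatePool.create(out)
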