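"""Centralized numerical tolerances and bound conventions.

All flux quantities are in mmol/gDW/h. Exchange reactions that the model
leaves uncapped receive a large finite bound (``FLUX_CAP``) so every LP
stays bounded and ineffective arbitrarily-high fluxes are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Default upper bound for an ordinary (non-exchange) reaction flux.
DEFAULT_UPPER_BOUND = 1000.0

#: Finite stand-in for an unbounded exchange flux; also the big-M constant
#: linking candidate fluxes to their binary inclusion variables in the MILP
#: oracle (it must exceed any feasible flux, and FLUX_CAP is the largest
#: bound any variable carries).
FLUX_CAP = 1.0e6


@dataclass(frozen=True)
class Tolerances:
    """Epsilon thresholds used across the package.

    Attributes
    ----------
    eps_balance:
        Maximum allowed steady-state residual |S v| per metabolite.
    eps_growth:
        Biomass flux above which a model is considered growing.
    eps_active:
        Candidate flux above which a candidate counts as active.
    """

    eps_balance: float = 1e-6
    eps_growth: float = 1e-6
    eps_active: float = 1e-8


DEFAULT_TOLERANCES = Tolerances()
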