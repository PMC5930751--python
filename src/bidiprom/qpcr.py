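"""ChIP-qPCR and RT-qPCR arithmetic.

``percent_input`` converts Ct values of the immunoprecipitated sample and
of an x% input aliquot into percent recovery of starting chromatin:

    %(ChIP/input) = 2 ** ((Ct_input - log2(x)) - Ct_chip) * 100

This is implemented exactly as the source formula is written. Note that
the common dilution-adjusted convention subtracts ``log2(100 / x)``
instead (so that a 1% input aliquot with Ct equal to the ChIP Ct means 1%
recovery, not 100%); that variant is available via
``convention="dilution_adjusted"``.

``occupancy`` is recovery at a specific locus over recovery at a
background locus; ``fold_change_ddct`` is the usual 2^-(ddCt) expression
fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct of the ChIP sample and of the x% input aliquot."""

    ct_chip: float
    ct_input: float
    x_percent: float

    def __post_init__(self) -> None:
        if not (0 < self.x_percent <= 100):
            raise ValueError(f"x_percent must be in (0, 100], got {self.x_percent}")
        for name, v in (("ct_chip", self.ct_chip), ("ct_input", self.ct_input)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")


def percent_input(m: QpcrMeasurement, convention: str = "as_published") -> float:
    """Percent of starting chromatin recovered by the immunoprecipitation."""
    if convention == "as_published":
        adjust = math.log2(m.x_percent)
    elif convention == "dilution_adjusted":
        adjust = math.log2(100.0 / m.x_percent)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return 2.0 ** ((m.ct_input - adjust) - m.ct_chip) * 100.0


def occupancy(pct_specific: float, pct_background: float) -> float:
    """Relative occupancy: specific-locus recovery over background recovery."""
    if pct_background <= 0:
        raise ValueError("background percent-input must be positive")
    return pct_specific / pct_background


def fold_change_ddct(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Expression fold change 2^-(ddCt), ddCt = dCt(condition) - dCt(control)."""
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
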