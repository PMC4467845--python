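"""Half-up decimal rounding helpers.

Printed survey tables round half-up at a fixed display precision, while
IEEE/numpy rounding is half-even; these helpers reproduce the printed
convention for table comparisons and display-precision aggregation.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_sig_figs"]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round to ``decimals`` decimal places with ties away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig_figs(value: float, sig: int) -> float:
    """Round to ``sig`` significant figures with ties away from zero."""
    if value == 0 or not math.isfinite(value):
        return value
    exponent = math.floor(math.log10(abs(value)))
    return round_half_up(value, sig - 1 - exponent)
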