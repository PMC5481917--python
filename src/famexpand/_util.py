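"""Small shared helpers: half-up rounding and percentage formatting."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (0.5 -> 1), not banker's rounding."""
    value = float(value)
    if not math.isfinite(value):
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def make_percentage(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100*numerator/denominator rounded half-up; NaN when denominator is 0."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, decimals)
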