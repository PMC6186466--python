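"""Half-up decimal rounding, matching how the published tables print values.

Python's built-in ``round`` is banker's rounding (0.5 ties go to even);
printed monetary and percentage cells in the reference tables are rounded
half-up, so a dedicated helper is used everywhere a displayed number is
produced. Internal arithmetic is never rounded.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round to ``decimals`` places with ties going away from zero.

    Uses Decimal on the shortest repr to avoid binary-float tie
    misclassification (e.g. 2.675 at 2 decimals).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
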