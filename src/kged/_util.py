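"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (half-up), as in printed tables.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    how results tables are conventionally rounded (e.g. 26.75 -> 26.8).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
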