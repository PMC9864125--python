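"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed-table conventions.

    Python's builtin ``round`` is banker's rounding; published tables
    round 0.165 up to 0.17, so presentation-layer rounding goes through
    ``decimal`` with ROUND_HALF_UP.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(
        Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    )
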