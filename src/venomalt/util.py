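"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float | Decimal, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed-table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: int, n: int, ndigits: int = 1) -> float:
    """100*k/n rounded half-up, computed on exact rationals."""
    if n == 0:
        raise ZeroDivisionError("percent undefined for n == 0")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(100) * Decimal(k) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))
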