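"""Centralized percentage/rounding conventions for reported numbers.

Overlap shares are printed as integer percents, composition percentages at
one decimal, lncRNA/isoform validation rates at two decimals. Rounding is
half-up (not banker's), done in decimal arithmetic so 100*601/3284 ->
18.3 exactly.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float | Decimal, decimals: int = 0) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    d = value if isinstance(value, Decimal) else Decimal(repr(value))
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def percent(part: int | float, whole: int | float, decimals: int = 1) -> float:
    """``100 * part / whole`` rounded half-up to ``decimals`` places."""
    if whole == 0:
        raise ZeroDivisionError("percent of an empty whole")
    exact = Decimal(100) * Decimal(str(part)) / Decimal(str(whole))
    return round_half_up(exact, decimals)


def integer_percent(part: int | float, whole: int | float) -> int:
    return int(percent(part, whole, decimals=0))
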