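"""Centralised rounding conventions for printed tables.

Summary tables use integer percentages, two-decimal means, and
three-decimal small percentages; ties round half-even. SNP rates (average
bases per SNP) truncate rather than round.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal


def round_half_even(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def pct_int(numerator: int, denominator: int) -> float:
    """Integer-precision percentage (e.g. 28 for 8,642,206/31,356,857)."""
    if denominator == 0:
        return 0.0
    return round_half_even(100.0 * numerator / denominator, 0)


def mean2(x: float) -> float:
    return round_half_even(x, 2)
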