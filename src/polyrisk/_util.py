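"""Small shared helpers: report-layer rounding and percentage arithmetic."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed clinical tables.

    Python's built-in ``round`` is banker's rounding (61.25 -> 61.2); published
    tables round halves up (61.25 -> 61.3), so report-layer percentages and
    odds ratios go through this helper instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded. Denominator must be > 0."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, ndigits)
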