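"""Shared numeric helpers (rounding conventions used across all reports)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, at ``ndigits`` decimals.

    All percentages and ratios in reports use half-up rounding; Python's
    built-in banker's rounding would print 9.55 -> 9.5 where the convention
    here requires 9.6.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, half-up rounded."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def ratio(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Plain ratio, half-up rounded (clade-richness style reporting)."""
    if denominator == 0:
        raise ZeroDivisionError("ratio with zero denominator")
    return round_half_up(numerator / denominator, ndigits)
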