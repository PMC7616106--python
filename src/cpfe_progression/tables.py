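"""Printed-precision helpers for report tables.

Report cells use round-half-up (0.5 always rounds away from zero), matching
how the clinical tables print percentages, rather than banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places with ties going away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Percentage ``100 * numerator / denominator`` at printed precision."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def format_count_percent(count: int, total: int, decimals: int = 0) -> str:
    """Render a table cell like ``51 (34%)`` / ``69 (50.74%)``."""
    p = percent(count, total, decimals)
    if decimals == 0:
        return f"{count} ({p:.0f}%)"
    return f"{count} ({p:.{decimals}f}%)"
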