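"""Numeric formatting conventions used across tables and reports.

Counts are paired with percentages rounded half-up to two decimals;
intakes print at two decimals and p-values at three, with values below
0.001 shown as "<0.001".
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent", "fmt_value", "fmt_percent_pair", "fmt_p", "fmt_median_iqr"]


def round_half_up(value: float, digits: int = 2) -> float:
    """Round with ties away from zero at ``digits`` decimals (half-up)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, digits: int = 2) -> float:
    """``100 * count / total`` rounded half-up; exact ratio first."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return round_half_up(100.0 * count / total, digits)


def fmt_value(value: float, digits: int = 2) -> str:
    return f"{round_half_up(value, digits):.{digits}f}"


def fmt_percent_pair(count: int, total: int) -> str:
    return f"{count} ({fmt_value(percent(count, total))}%)"


def fmt_p(p: float) -> str:
    if p < 0.001:
        return "<0.001"
    return f"{round_half_up(p, 3):.3f}"


def fmt_median_iqr(median: float, p25: float, p75: float, digits: int = 2) -> str:
    return f"{fmt_value(median, digits)} ({fmt_value(p25, digits)}, {fmt_value(p75, digits)})"
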