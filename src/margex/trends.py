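"""Yearly percentage series and unweighted least-squares trend slopes."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .aggregation import GroupStats

OUTCOMES = ("pvalue", "article")


@dataclass(frozen=True)
class TrendFit:
    group: str
    outcome: str
    points: tuple[tuple[int, float], ...]
    slope: float  # percentage points per calendar year
    intercept: float  # fitted percentage at the origin year
    origin: int
    n_years: int
    stderr: Optional[float]  # residual-based SE of the slope (None if n <= 2)


def yearly_series(
    stats: Sequence[GroupStats], outcome: str = "pvalue", group: Optional[str] = None
) -> list[tuple[int, float]]:
    """(year, percentage) points for one group; undefined years are omitted.

    A year whose denominator is zero has no percentage and contributes no
    point — it is never imputed as 0.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    pts = []
    groups = {s.group for s in stats if group is None or s.group == group}
    if group is None and len(groups) > 1:
        raise ValueError(f"stats span several groups {sorted(groups)}; pass group=")
    for s in stats:
        if group is not None and s.group != group:
            continue
        if s.year is None:
            continue
        pct = s.pct_marginal if outcome == "pvalue" else s.pct_articles_marginal
        if pct is None:
            continue
        pts.append((s.year, float(pct)))
    pts.sort()
    return pts


def ols_slope(
    points: Sequence[tuple[int, float]],
    group: str = "all",
    outcome: str = "pvalue",
    origin: int = 1985,
) -> TrendFit:
    """Simple unweighted least-squares line through (year, percentage).

    slope = sum((x - xbar)(y - ybar)) / sum((x - xbar)^2) with x the
    calendar year; the intercept is reported at ``origin`` for readability.
    Requires at least two distinct years.
    """
    xs = [float(x) for x, _ in points]
    ys = [float(y) for _, y in points]
    n = len(points)
    if n < 2 or len(set(xs)) < 2:
        raise ValueError("trend fit needs >= 2 points with >= 2 distinct years")
    xbar = sum(xs) / n
    ybar = sum(ys) / n
    sxx = sum((x - xbar) ** 2 for x in xs)
    sxy = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys))
    slope = sxy / sxx
    intercept = ybar + slope * (origin - xbar)
    stderr = None
    if n > 2:
        ssr = sum((y - (ybar + slope * (x - xbar))) ** 2 for x, y in zip(xs, ys))
        stderr = math.sqrt(ssr / (n - 2) / sxx)
    return TrendFit(
        group=group,
        outcome=outcome,
        points=tuple((int(x), float(y)) for x, y in points),
        slope=slope,
        intercept=intercept,
        origin=origin,
        n_years=n,
        stderr=stderr,
    )


def fit_trend(
    stats: Sequence[GroupStats],
    group: str,
    outcome: str = "pvalue",
    origin: int = 1985,
) -> TrendFit:
    """Convenience: series + fit for one group out of a per-year stats set."""
    pts = yearly_series(stats, outcome=outcome, group=group)
    return ols_slope(pts, group=group, outcome=outcome, origin=origin)


def fit_all_trends(
    stats: Sequence[GroupStats], origin: int = 1985
) -> list[TrendFit]:
    """Both outcome-level fits for every group with enough yearly points."""
    fits = []
    for group in sorted({s.group for s in stats}):
        for outcome in OUTCOMES:
            pts = yearly_series(stats, outcome=outcome, group=group)
            if len(pts) >= 2 and len({x for x, _ in pts}) >= 2:
                fits.append(ols_slope(pts, group=group, outcome=outcome, origin=origin))
    return fits
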