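"""Grouped outcome percentages, per-article ratios, and binomial CIs.

Two outcome levels are computed per group cell:

* p-value level: percentage of in-range p-values (.05 < p <= .10) labeled
  marginal, denominator = in-range count;
* article level: percentage of articles with at least one marginal in-range
  p-value, denominator = ALL articles containing p-values (not only those
  with in-range values — many articles have none, which deliberately
  inflates this denominator).

Grouping by discipline uses multi-membership: a row counts once in every
discipline its journal belongs to, so discipline counts may sum to more
than the overall count.

Input rows are the post-cascade record set.  Rows dropped for missing
metadata, non-numeric values, or core-only journals do not count as
p-values; rows merely out of range DO count toward the p-value and article
totals (only the in-range columns exclude them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import norm

from .corpus_io import RecordRow

_COUNTED_STATUSES = {"retained", "out_of_range"}

ALL_YEARS: None = None


def wald_ci(p_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial interval on the percentage scale.

    bounds = 100 * (p_hat +/- z * sqrt(p_hat (1 - p_hat) / n)), clamped to
    [0, 100]; z is the standard-normal (1 + level)/2 quantile.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must be in [0, 1]")
    z = norm.ppf(0.5 + level / 2)
    half = z * (p_hat * (1 - p_hat) / n) ** 0.5
    return (max(0.0, 100 * (p_hat - half)), min(100.0, 100 * (p_hat + half)))


def wilson_ci(p_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval on the percentage scale."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z = norm.ppf(0.5 + level / 2)
    z2 = z * z
    denom = 1 + z2 / n
    center = (p_hat + z2 / (2 * n)) / denom
    half = (z / denom) * (p_hat * (1 - p_hat) / n + z2 / (4 * n * n)) ** 0.5
    return (max(0.0, 100 * (center - half)), min(100.0, 100 * (center + half)))


_CI_METHODS = {"wald": wald_ci, "wilson": wilson_ci}


def proportion_ci(
    p_hat: float, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    try:
        fn = _CI_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown CI method {method!r} (use 'wald' or 'wilson')")
    return fn(p_hat, n, level)


@dataclass(frozen=True)
class ArticleFlags:
    has_p: bool
    has_inrange: bool
    has_marginal: bool

    def __post_init__(self) -> None:
        if self.has_marginal and not self.has_inrange:
            raise ValueError("has_marginal implies has_inrange")
        if self.has_inrange and not self.has_p:
            raise ValueError("has_inrange implies has_p")


def per_article_rollup(rows: Iterable[RecordRow]) -> dict[str, ArticleFlags]:
    """One flag record per article: contains p-values / in-range / marginal."""
    acc: dict[str, list[bool]] = {}
    for r in rows:
        if r.filter_status not in _COUNTED_STATUSES:
            continue
        cur = acc.setdefault(r.article_id, [False, False, False])
        cur[0] = True
        if r.filter_status == "retained":
            cur[1] = True
            if r.is_marginal:
                cur[2] = True
    return {a: ArticleFlags(*flags) for a, flags in acc.items()}


@dataclass(frozen=True)
class GroupStats:
    """Counts, percentages and CI bounds for one (group, year) cell."""

    group: str
    year: Optional[int]
    n_journals: int
    n_articles_with_p: int
    n_pvalues: int
    n_inrange: int
    n_articles_with_inrange: int
    n_marginal: int
    n_articles_marginal: int
    pct_marginal: Optional[float]
    ci_marginal: Optional[tuple[float, float]]
    pct_articles_marginal: Optional[float]
    ci_articles_marginal: Optional[tuple[float, float]]
    pvalues_per_article: Optional[float]
    inrange_per_article: Optional[float]


def _cell_stats(
    group: str,
    year: Optional[int],
    rows: Sequence[RecordRow],
    ci_method: str,
    level: float,
) -> GroupStats:
    journals = {r.journal_canonical or r.journal_raw for r in rows}
    articles = {r.article_id for r in rows}
    inrange = [r for r in rows if r.filter_status == "retained"]
    marginal = [r for r in inrange if r.is_marginal]
    arts_inrange = {r.article_id for r in inrange}
    arts_marginal = {r.article_id for r in marginal}

    n_art, n_p, n_in = len(articles), len(rows), len(inrange)
    n_marg, n_am = len(marginal), len(arts_marginal)

    if n_in > 0:
        p1 = n_marg / n_in
        pct_marginal = 100 * p1
        ci_marg = proportion_ci(p1, n_in, level, ci_method)
    else:
        pct_marginal, ci_marg = None, None
    if n_art > 0:
        p2 = n_am / n_art
        pct_articles = 100 * p2
        ci_art = proportion_ci(p2, n_art, level, ci_method)
    else:
        pct_articles, ci_art = None, None

    return GroupStats(
        group=group,
        year=year,
        n_journals=len(journals - {None}),
        n_articles_with_p=n_art,
        n_pvalues=n_p,
        n_inrange=n_in,
        n_articles_with_inrange=len(arts_inrange),
        n_marginal=n_marg,
        n_articles_marginal=n_am,
        pct_marginal=pct_marginal,
        ci_marginal=ci_marg,
        pct_articles_marginal=pct_articles,
        ci_articles_marginal=ci_art,
        pvalues_per_article=(n_p / n_art) if n_art else None,
        inrange_per_article=(n_in / n_art) if n_art else None,
    )


def _group_rows(rows: Sequence[RecordRow], grouping: str) -> dict[str, list[RecordRow]]:
    if grouping == "overall":
        return {"all": list(rows)}
    if grouping == "journal":
        out: dict[str, list[RecordRow]] = {}
        for r in rows:
            key = r.journal_canonical or r.journal_raw or "<unknown>"
            out.setdefault(key, []).append(r)
        return dict(sorted(out.items()))
    if grouping == "discipline":
        disciplines: set[str] = set()
        for r in rows:
            disciplines.update(r.discipline_flags)
        out = {d: [r for r in rows if r.discipline_flags.get(d)] for d in sorted(disciplines)}
        return out
    raise ValueError(f"unknown grouping {grouping!r} (use overall|journal|discipline)")


def summarize(
    rows: Iterable[RecordRow],
    grouping: str = "overall",
    per_year: bool = False,
    ci_method: str = "wald",
    level: float = 0.95,
) -> list[GroupStats]:
    """GroupStats for every (group, year) cell under the chosen grouping.

    With ``per_year`` the cells use the article's publication year; rows
    with no resolved year are excluded from yearly cells (never imputed)
    but are kept in all-years cells.
    """
    counted = [r for r in rows if r.filter_status in _COUNTED_STATUSES]
    stats: list[GroupStats] = []
    for group, grows in _group_rows(counted, grouping).items():
        if not per_year:
            stats.append(_cell_stats(group, ALL_YEARS, grows, ci_method, level))
            continue
        by_year: dict[int, list[RecordRow]] = {}
        for r in grows:
            if r.year is not None:
                by_year.setdefault(r.year, []).append(r)
        for year in sorted(by_year):
            stats.append(_cell_stats(group, year, by_year[year], ci_method, level))
    return stats


def stats_to_frame(stats: Sequence[GroupStats]) -> pd.DataFrame:
    """Tabular view of GroupStats (CI bounds split into separate columns)."""
    recs = []
    for s in stats:
        recs.append(
            {
                "group": s.group,
                "year": s.year,
                "n_journals": s.n_journals,
                "n_articles_with_p": s.n_articles_with_p,
                "n_pvalues": s.n_pvalues,
                "n_inrange": s.n_inrange,
                "n_articles_with_inrange": s.n_articles_with_inrange,
                "n_marginal": s.n_marginal,
                "n_articles_marginal": s.n_articles_marginal,
                "pct_marginal": s.pct_marginal,
                "ci_marginal_low": s.ci_marginal[0] if s.ci_marginal else None,
                "ci_marginal_high": s.ci_marginal[1] if s.ci_marginal else None,
                "pct_articles_marginal": s.pct_articles_marginal,
                "ci_articles_low": s.ci_articles_marginal[0] if s.ci_articles_marginal else None,
                "ci_articles_high": s.ci_articles_marginal[1] if s.ci_articles_marginal else None,
                "pvalues_per_article": s.pvalues_per_article,
                "inrange_per_article": s.inrange_per_article,
            }
        )
    return pd.DataFrame.from_records(recs)


def frame_to_stats(df: pd.DataFrame) -> list[GroupStats]:
    """Inverse of :func:`stats_to_frame` (used by the trend CLI stage)."""
    out = []
    for rec in df.to_dict("records"):
        def _opt(x):
            return None if pd.isna(x) else float(x)

        ci_m = (
            (float(rec["ci_marginal_low"]), float(rec["ci_marginal_high"]))
            if not pd.isna(rec["ci_marginal_low"])
            else None
        )
        ci_a = (
            (float(rec["ci_articles_low"]), float(rec["ci_articles_high"]))
            if not pd.isna(rec["ci_articles_low"])
            else None
        )
        out.append(
            GroupStats(
                group=str(rec["group"]),
                year=None if pd.isna(rec["year"]) else int(rec["year"]),
                n_journals=int(rec["n_journals"]),
                n_articles_with_p=int(rec["n_articles_with_p"]),
                n_pvalues=int(rec["n_pvalues"]),
                n_inrange=int(rec["n_inrange"]),
                n_articles_with_inrange=int(rec["n_articles_with_inrange"]),
                n_marginal=int(rec["n_marginal"]),
                n_articles_marginal=int(rec["n_articles_marginal"]),
                pct_marginal=_opt(rec["pct_marginal"]),
                ci_marginal=ci_m,
                pct_articles_marginal=_opt(rec["pct_articles_marginal"]),
                ci_articles_marginal=ci_a,
                pvalues_per_article=_opt(rec["pvalues_per_article"]),
                inrange_per_article=_opt(rec["inrange_per_article"]),
            )
        )
    return out
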