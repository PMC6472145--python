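import math
import random

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from margex.aggregation import (
    ArticleFlags,
    per_article_rollup,
    proportion_ci,
    summarize,
    wald_ci,
    wilson_ci,
)
from margex.rounding import round_half_up, round_ratio

from conftest import make_row


class TestWaldCI:
    def test_degenerate_zero_proportion(self):
        assert wald_ci(0.0, 50) == (0.0, 0.0)

    def test_degenerate_one_proportion(self):
        assert wald_ci(1.0, 50) == (100.0, 100.0)

    def test_clamped_to_percentage_scale(self):
        lo, hi = wald_ci(0.01, 5)
        assert lo == 0.0 and 0 < hi <= 100

    def test_closed_form(self):
        # independent closed-form evaluation with z = Phi^-1(0.975)
        p, n = 0.37, 812
        z = 1.959963984540054
        half = z * math.sqrt(p * (1 - p) / n)
        lo, hi = wald_ci(p, n)
        assert lo == pytest.approx(100 * (p - half), abs=1e-10)
        assert hi == pytest.approx(100 * (p + half), abs=1e-10)

    def test_against_statsmodels_on_integer_counts(self):
        rng = random.Random(5)
        for _ in range(50):
            n = rng.randrange(10, 5000)
            k = rng.randrange(1, n)
            lo, hi = wald_ci(k / n, n)
            sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="normal")
            assert lo == pytest.approx(100 * sm_lo, abs=1e-8)
            assert hi == pytest.approx(100 * sm_hi, abs=1e-8)

    def test_width_decreasing_in_n(self):
        widths = [wald_ci(0.3, n)[1] - wald_ci(0.3, n)[0] for n in (10, 100, 1000, 10000)]
        assert widths == sorted(widths, reverse=True)
        assert len(set(widths)) == len(widths)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wald_ci(0.5, 0)
        with pytest.raises(ValueError):
            wald_ci(1.5, 10)


class TestWilsonCI:
    def test_against_statsmodels(self):
        rng = random.Random(9)
        for _ in range(50):
            n = rng.randrange(10, 5000)
            k = rng.randrange(0, n + 1)
            lo, hi = wilson_ci(k / n, n)
            sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(100 * sm_lo, abs=1e-8)
            assert hi == pytest.approx(100 * sm_hi, abs=1e-8)

    def test_method_dispatch(self):
        assert proportion_ci(0.4, 100, method="wilson") == wilson_ci(0.4, 100)
        with pytest.raises(ValueError):
            proportion_ci(0.4, 100, method="bayes")


class TestRollup:
    def test_three_inrange_one_marginal(self):
        rows = [
            make_row(value_text=".06", is_marginal=True),
            make_row(value_text=".07", is_marginal=False),
            make_row(value_text=".08", is_marginal=False),
        ]
        flags = per_article_rollup(rows)
        assert flags == {"a1": ArticleFlags(True, True, True)}

    def test_only_out_of_range(self):
        rows = [make_row(value_text=".2", filter_status="out_of_range")]
        assert per_article_rollup(rows) == {"a1": ArticleFlags(True, False, False)}

    def test_inrange_none_marginal(self):
        rows = [
            make_row(value_text=".06", is_marginal=False),
            make_row(value_text=".07", is_marginal=False),
        ]
        assert per_article_rollup(rows) == {"a1": ArticleFlags(True, True, False)}

    def test_excluded_rows_do_not_count(self):
        rows = [make_row(value_text=".", value=None, filter_status="nonnumeric")]
        assert per_article_rollup(rows) == {}

    def test_implication_chain_enforced(self):
        with pytest.raises(ValueError):
            ArticleFlags(True, False, True)


def _labeled_fixture():
    """Three articles across two journals and two disciplines."""
    flags_a = {"social": True, "clinical": False}
    flags_b = {"social": True, "clinical": True}
    rows = [
        # article x, Journal A (social): 2 in-range (1 marginal), 1 out
        make_row("x", ".06", journal="Journal A", journal_canonical="Journal A",
                 discipline_flags=flags_a, is_marginal=True, year=1990),
        make_row("x", ".09", journal="Journal A", journal_canonical="Journal A",
                 discipline_flags=flags_a, is_marginal=False, year=1990, offset=500),
        make_row("x", ".3", journal="Journal A", journal_canonical="Journal A",
                 discipline_flags=flags_a, filter_status="out_of_range", year=1990, offset=1000),
        # article y, Journal B (social+clinical): 1 in-range, not marginal
        make_row("y", ".07", journal="Journal B", journal_canonical="Journal B",
                 discipline_flags=flags_b, is_marginal=False, year=1991),
        # article z, Journal B: p-values but none in range
        make_row("z", ".01", journal="Journal B", journal_canonical="Journal B",
                 discipline_flags=flags_b, filter_status="out_of_range", year=1991),
        make_row("z", ".4", journal="Journal B", journal_canonical="Journal B",
                 discipline_flags=flags_b, filter_status="out_of_range", year=1991, offset=500),
        # excluded row: must not count anywhere
        make_row("w", ".", value=None, journal="Journal A", filter_status="nonnumeric"),
    ]
    return rows


class TestSummarize:
    def test_overall_counts(self):
        (s,) = summarize(_labeled_fixture(), "overall")
        assert s.n_pvalues == 6  # the non-numeric row does not count
        assert s.n_articles_with_p == 3
        assert s.n_inrange == 3
        assert s.n_articles_with_inrange == 2
        assert s.n_marginal == 1
        assert s.n_articles_marginal == 1
        assert s.pct_marginal == pytest.approx(100 / 3)
        # article-level denominator is ALL articles with p-values, not just
        # those with in-range values
        assert s.pct_articles_marginal == pytest.approx(100 / 3)
        assert s.pvalues_per_article == pytest.approx(2.0)
        assert s.inrange_per_article == pytest.approx(1.0)

    def test_journal_grouping_conserves_pvalues(self):
        stats = summarize(_labeled_fixture(), "journal")
        assert sum(s.n_pvalues for s in stats) == 6

    def test_discipline_multi_membership(self):
        stats = {s.group: s for s in summarize(_labeled_fixture(), "discipline")}
        assert stats["social"].n_pvalues == 6  # every row is social
        assert stats["clinical"].n_pvalues == 3  # Journal B rows only
        # multi-membership: discipline totals exceed the overall total
        assert sum(s.n_pvalues for s in stats.values()) > 6

    def test_group_without_inrange_emits_missing_not_zero(self):
        rows = [make_row("z", ".4", filter_status="out_of_range")]
        (s,) = summarize(rows, "overall")
        assert s.pct_marginal is None
        assert s.ci_marginal is None

    def test_per_year_excludes_unresolved_years(self):
        rows = _labeled_fixture()
        rows[0].year = None
        yearly = summarize(rows, "overall", per_year=True)
        assert all(s.year is not None for s in yearly)
        assert sum(s.n_pvalues for s in yearly) == 5  # the year-less row dropped
        (all_years,) = summarize(rows, "overall")
        assert all_years.n_pvalues == 6  # but kept in the all-years cell

    def test_ci_brackets_point_estimate(self):
        for s in summarize(_labeled_fixture(), "discipline"):
            if s.pct_marginal is not None:
                lo, hi = s.ci_marginal
                assert 0 <= lo <= s.pct_marginal <= hi <= 100

    def test_unknown_grouping(self):
        with pytest.raises(ValueError):
            summarize([], "continent")


def _brute_force_pct(rows, group_filter):
    grows = [r for r in rows if group_filter(r) and r.filter_status in ("retained", "out_of_range")]
    inr = [r for r in grows if r.filter_status == "retained"]
    marg = [r for r in inr if r.is_marginal]
    return 100 * len(marg) / len(inr) if inr else None


def test_group_percentage_matches_brute_force_on_random_fixtures():
    rng = random.Random(123)
    journals = ["Journal A", "Journal B", "Journal C"]
    disc_of = {
        "Journal A": {"social": True, "clinical": False},
        "Journal B": {"social": True, "clinical": True},
        "Journal C": {"social": False, "clinical": True},
    }
    for trial in range(20):
        rows = []
        for i in range(rng.randrange(5, 80)):
            j = rng.choice(journals)
            status = rng.choice(["retained", "retained", "out_of_range", "nonnumeric"])
            rows.append(
                make_row(
                    article_id=f"a{rng.randrange(10)}",
                    journal=j,
                    journal_canonical=j,
                    discipline_flags=disc_of[j],
                    filter_status=status,
                    is_marginal=rng.random() < 0.4 if status == "retained" else None,
                    offset=i,
                )
            )
        for s in summarize(rows, "journal"):
            expected = _brute_force_pct(rows, lambda r, g=s.group: (r.journal_canonical or r.journal_raw) == g)
            assert (s.pct_marginal is None) == (expected is None)
            if expected is not None:
                assert s.pct_marginal == pytest.approx(expected, abs=1e-10)
        for s in summarize(rows, "discipline"):
            expected = _brute_force_pct(rows, lambda r, g=s.group: r.discipline_flags.get(g, False))
            if expected is not None:
                assert s.pct_marginal == pytest.approx(expected, abs=1e-10)


class TestRounding:
    def test_half_up_not_bankers(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.135, 2) == 0.14
        assert round_half_up(2.5, 0) == 3.0

    def test_ratio_exact_decimal(self):
        # 777596 / 44200 = 17.59266...; binary floats would be fine here,
        # but the contract is exact decimal division
        assert round_ratio(777596, 44200) == 17.59
        assert round_ratio(1, 8, ndigits=2) == 0.13  # 0.125 rounds up
        assert round_ratio(51, 790206, scale=100) == 0.01
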