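"""Contingency-table statistics: PRR, Yates chi-square, Fisher, CIs, signals."""

import math
from fractions import Fraction
from math import comb

import pytest
import scipy.stats
from hypothesis import assume, given
from hypothesis import strategies as st

from pvsignal.stats import (
    ContingencyTable,
    SignalCriteria,
    ZeroMarginError,
    analyze_table,
    chi2_yates,
    classify_signal,
    exact_or_ci,
    fisher_exact_two_sided,
    format_chi2,
    format_prr,
    prr,
    prr_wald_ci,
)

cells = st.integers(min_value=0, max_value=60)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


def nonzero_margin_tables(draw):
    t = draw(tables)
    assume(t.a + t.b > 0 and t.c + t.d > 0 and t.a + t.c > 0 and t.b + t.d > 0)
    return t


valid_tables = st.composite(nonzero_margin_tables)()

# Published 2x2 cells for the dopamine-agonist / behavioral-addiction
# analysis (2004 and 2007 FAERS initial reports) with the statistics they
# yield; chi-square display values verified against the closed form.
PUBLISHED_TABLES = [
    ("pathological_gambling-2004", 28, 5, 899, 198_822, "1201", "4906.9"),
    ("pathological_gambling-2007", 170, 14, 2_175, 251_803, "1304", "16752.7"),
    ("binge_eating-2004", 0, 251, 927, 198_576, "0", "0.4"),
    ("binge_eating-2007", 6, 322, 2_339, 251_495, "2", "2.0"),
    ("hypersexuality-2004", 4, 87, 923, 198_740, "10", "22.5"),
    ("hypersexuality-2007", 30, 65, 2_315, 251_752, "50", "943.8"),
]


@pytest.mark.parametrize("label,a,b,c,d,prr_disp,chi2_disp", PUBLISHED_TABLES)
def test_published_tables_reproduce(label, a, b, c, d, prr_disp, chi2_disp):
    t = ContingencyTable(a, b, c, d)
    assert format_prr(prr(t)) == prr_disp
    assert format_chi2(chi2_yates(t)) == chi2_disp


class TestPrr:
    def test_zero_exposed_cases_gives_zero(self):
        assert prr(ContingencyTable(0, 251, 927, 198_576)) == 0.0

    def test_zero_unexposed_cases_gives_infinity(self):
        assert math.isinf(prr(ContingencyTable(3, 0, 10, 100)))

    @pytest.mark.parametrize("t", [ContingencyTable(0, 5, 0, 10), ContingencyTable(5, 0, 10, 0)])
    def test_zero_exposure_margin_raises(self, t):
        with pytest.raises(ZeroMarginError):
            prr(t)

    @given(valid_tables)
    def test_above_one_iff_cross_product_inequality(self, t):
        assume(t.a > 0 and t.b > 0)
        assert (prr(t) > 1) == (t.a * (t.b + t.d) > t.b * (t.a + t.c))


class TestChi2Yates:
    def test_symmetric_table_clamps_to_zero(self):
        assert chi2_yates(ContingencyTable(5, 5, 5, 5)) == 0.0

    def test_zero_margin_raises(self):
        with pytest.raises(ZeroMarginError):
            chi2_yates(ContingencyTable(0, 0, 5, 5))

    @given(valid_tables)
    def test_invariant_under_column_swap(self, t):
        swapped = ContingencyTable(t.b, t.a, t.d, t.c)
        assert chi2_yates(t) == pytest.approx(chi2_yates(swapped), rel=1e-12)

    @given(valid_tables)
    def test_invariant_under_transposition(self, t):
        transposed = ContingencyTable(t.a, t.c, t.b, t.d)
        assert chi2_yates(t) == pytest.approx(chi2_yates(transposed), rel=1e-12)

    @given(valid_tables)
    def test_agrees_with_scipy_beyond_clamp(self, t):
        # scipy's correction moves each cell 0.5 toward expectation and can
        # overshoot where the clamp zeroes the statistic, so compare only
        # where the corrected difference is positive.
        assume(abs(t.a * t.d - t.b * t.c) > t.n / 2)
        ref = scipy.stats.chi2_contingency(t.as_array(), correction=True).statistic
        assert chi2_yates(t) == pytest.approx(ref, rel=1e-10)


def fisher_oracle(t: ContingencyTable) -> float:
    """Exact-rational enumeration of the two-sided Fisher p-value."""
    n, K, m = t.n, t.a + t.b, t.a + t.c
    if K == 0 or m == 0 or K == n or m == n:
        return 1.0
    denom = comb(n, m)
    lo, hi = max(0, m - (n - K)), min(m, K)
    probs = {k: Fraction(comb(K, k) * comb(n - K, m - k), denom) for k in range(lo, hi + 1)}
    cutoff = probs[t.a] * Fraction(10**7 + 1, 10**7)
    return float(sum(p for p in probs.values() if p <= cutoff))


class TestFisher:
    def test_tiny_table_enumeration(self):
        # margins (2,2;2,2) admit three tables with point probs 1/6, 4/6, 1/6
        assert fisher_exact_two_sided(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 3, abs=1e-12)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 0, 5, 5)) == 1.0

    def test_published_cell_is_significant(self):
        assert fisher_exact_two_sided(ContingencyTable(28, 5, 899, 198_822)) < 0.001

    @given(tables)
    def test_matches_exact_enumeration(self, t):
        assume(t.n > 0)
        assert fisher_exact_two_sided(t) == pytest.approx(fisher_oracle(t), abs=1e-10)

    @given(tables)
    def test_matches_scipy(self, t):
        assume(t.n > 0)
        ref = scipy.stats.fisher_exact(t.as_array(), alternative="two-sided").pvalue
        assert fisher_exact_two_sided(t) == pytest.approx(ref, rel=1e-6, abs=1e-12)


class TestWaldCI:
    def test_frozen_value(self):
        # direct evaluation of exp(ln PRR +/- z*sqrt(1/a - 1/(a+c) + 1/b - 1/(b+d)))
        ci = prr_wald_ci(ContingencyTable(30, 65, 2_315, 251_752), level=0.95)
        assert ci.low == pytest.approx(32.218, abs=0.01)
        assert ci.high == pytest.approx(76.242, abs=0.01)
        assert ci.method == "wald-log-prr"

    @given(valid_tables)
    def test_contains_point_estimate(self, t):
        assume(t.a > 0 and t.b > 0)
        ci = prr_wald_ci(t, level=0.95)
        assert ci.low <= prr(t) <= ci.high

    def test_width_monotone_in_level(self):
        t = ContingencyTable(10, 20, 100, 1000)
        widths = [
            prr_wald_ci(t, level).high - prr_wald_ci(t, level).low
            for level in (0.8, 0.9, 0.95, 0.99)
        ]
        assert widths == sorted(widths)

    def test_zero_cell_not_computable(self):
        assert prr_wald_ci(ContingencyTable(0, 5, 10, 100)) is None
        assert prr_wald_ci(ContingencyTable(5, 0, 10, 100)) is None


def nch_tail_probs(t: ContingencyTable, psi: float) -> tuple[float, float]:
    """Brute-force noncentral hypergeometric tails P(X >= a), P(X <= a)."""
    n, K, m = t.n, t.a + t.b, t.a + t.c
    lo, hi = max(0, m - (n - K)), min(m, K)
    weights = {k: comb(m, k) * comb(n - m, K - k) * psi**k for k in range(lo, hi + 1)}
    total = sum(weights.values())
    ge = sum(w for k, w in weights.items() if k >= t.a) / total
    le = sum(w for k, w in weights.items() if k <= t.a) / total
    return ge, le


class TestExactConditionalCI:
    def test_zero_cell_has_finite_upper_bound(self):
        ci = exact_or_ci(ContingencyTable(0, 251, 927, 198_576), level=0.95)
        assert ci.low == 0.0
        assert 0 < ci.high < math.inf
        assert ci.method == "exact-conditional-or"

    @pytest.mark.parametrize(
        "t",
        [
            ContingencyTable(4, 8, 6, 12),
            ContingencyTable(7, 2, 3, 11),
            ContingencyTable(1, 9, 5, 5),
        ],
    )
    def test_endpoints_invert_the_tails(self, t):
        # at the limits, the corresponding noncentral hypergeometric tail
        # probability equals alpha/2 (checked against brute-force pmf)
        ci = exact_or_ci(t, level=0.95)
        assert nch_tail_probs(t, ci.low)[0] == pytest.approx(0.025, abs=1e-6)
        assert nch_tail_probs(t, ci.high)[1] == pytest.approx(0.025, abs=1e-6)

    @pytest.mark.parametrize("t", [ContingencyTable(4, 8, 6, 12), ContingencyTable(9, 3, 2, 10)])
    def test_brackets_the_odds_ratio(self, t):
        ci = exact_or_ci(t, level=0.95)
        or_hat = (t.a * t.d) / (t.b * t.c)
        assert ci.low <= or_hat <= ci.high

    def test_nesting_of_levels(self):
        t = ContingencyTable(4, 8, 6, 12)
        ci95, ci99 = exact_or_ci(t, 0.95), exact_or_ci(t, 0.99)
        assert ci99.low <= ci95.low and ci95.high <= ci99.high


class TestSignalClassification:
    @pytest.mark.parametrize(
        "a,prr_v,chi2_v,expected",
        [
            (4, 10.0, 22.5, True),  # weak but genuine signal
            (6, 2.0, 2.0, False),  # chi-square below threshold
            (2, 100.0, 50.0, False),  # fewer than 3 cases
            (3, math.inf, 4.0, True),  # infinite PRR passes the PRR criterion
            (3, 1.9, 50.0, False),
        ],
    )
    def test_evans_criteria(self, a, prr_v, chi2_v, expected):
        t = ContingencyTable(a, 10, 10, 1000)
        assert classify_signal(t, prr_v, chi2_v, SignalCriteria()) is expected

    def test_monotone_in_exposed_cases(self):
        b, c, d = 10, 50, 10_000
        flags = []
        for a in range(1, 40):
            t = ContingencyTable(a, b, c, d)
            flags.append(classify_signal(t, prr(t), chi2_yates(t)))
        first_true = flags.index(True)
        assert all(flags[first_true:])

    def test_analyze_table_degenerate_margins(self):
        res = analyze_table(ContingencyTable(0, 0, 3, 7))
        assert res.prr == 0.0  # a = 0 with valid exposure margins
        assert res.chi2_yates is None
        assert res.fisher_p == 1.0
        assert res.signal is False
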