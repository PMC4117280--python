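"""Disproportionality statistics for 2×2 report contingency tables.

The unit of counting is the report.  For a drug set D and a reaction term
group G, each report falls in exactly one cell:

====================  =================  =====================
                      mentions G          no G term
====================  =================  =====================
mentions a drug in D  a (exposed case)   c (exposed non-case)
no drug in D          b (unexposed case) d (unexposed non-case)
====================  =================  =====================

The proportional reporting ratio PRR = [a/(a+c)] / [b/(b+d)] compares how
often the reaction is reported for the drug against how often it is
reported for everything else.  A pair is flagged as a signal by the Evans
criteria when a >= 3, PRR >= 2, and the Yates continuity-corrected
chi-square >= 4 — a screening threshold, not evidence of causation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .records import ReportDatabase
from .vocabulary import DEFAULT_MAX_EDIT_DISTANCE, DrugLexicon, TermGroup, resolve_report_exposures

#: Relative tolerance when comparing hypergeometric point probabilities in
#: the two-sided Fisher test (tables whose probability exceeds the observed
#: one by less than this factor still count as "as extreme").
FISHER_RELATIVE_TOL = 1e-7


class ZeroMarginError(ValueError):
    """A statistic is undefined because a table margin is zero."""


class NonEvaluableGroupError(ValueError):
    """The term group carries no vocabulary terms; report a dash row instead."""


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts a, b, c, d (see module docstring)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def exposed_total(self) -> int:
        return self.a + self.c

    @property
    def case_total(self) -> int:
        return self.a + self.b

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class SignalCriteria:
    """Evans screening thresholds: minimum case count, PRR, and Yates chi-square."""

    min_cases: int = 3
    min_prr: float = 2.0
    min_chi2: float = 4.0

    def __post_init__(self) -> None:
        if self.min_cases <= 0 or self.min_prr <= 0 or self.min_chi2 <= 0:
            raise ValueError("signal criteria thresholds must be positive")


@dataclass(frozen=True)
class ConfidenceInterval:
    low: float
    high: float
    level: float
    method: str


@dataclass(frozen=True)
class DisproportionalityResult:
    """All statistics for one drug-set × term-group × period cell."""

    table: ContingencyTable
    prr: float
    chi2_yates: float | None
    fisher_p: float
    ci: ConfidenceInterval | None
    ci_exact: ConfidenceInterval | None
    signal: bool

    @property
    def n_cases(self) -> int:
        return self.table.a


def build_contingency(
    db: ReportDatabase,
    ingredients: set[str] | frozenset[str],
    group: TermGroup,
    lexicon: DrugLexicon,
    max_edit_distance: int = DEFAULT_MAX_EDIT_DISTANCE,
) -> ContingencyTable:
    """Count reports of ``db`` into the 2×2 table for ``ingredients`` × ``group``.

    ``db`` should already be restricted to initial reports of one period.
    A report is exposed when any of its drug mentions resolves to one of the
    target ingredients (any role), and is a case when any of its reaction
    terms belongs to the group.  Each report counts exactly once.
    """
    if not group.evaluable:
        raise NonEvaluableGroupError(
            f"group {group.group_id!r} has no vocabulary terms; mark the row non-evaluable"
        )
    ingredients = frozenset(ingredients)
    terms = group.terms
    a = b = c = d = 0
    cache: dict[str, str | None] = {}
    for rec in db:
        exposed = bool(
            resolve_report_exposures(rec, lexicon, max_edit_distance, _cache=cache) & ingredients
        )
        case = not terms.isdisjoint(rec.reaction_terms())
        if exposed:
            if case:
                a += 1
            else:
                c += 1
        elif case:
            b += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def prr(t: ContingencyTable) -> float:
    """Proportional reporting ratio [a/(a+c)] / [b/(b+d)].

    Zero exposed cases give 0; zero unexposed cases with a > 0 give
    ``inf`` (no continuity corrections anywhere).
    """
    if t.exposed_total == 0 or t.b + t.d == 0:
        raise ZeroMarginError("PRR undefined: an exposure margin is zero")
    if t.a == 0:
        return 0.0
    if t.b == 0:
        return math.inf
    return (t.a / t.exposed_total) / (t.b / (t.b + t.d))


def chi2_yates(t: ContingencyTable) -> float:
    """Yates continuity-corrected Pearson chi-square for the 2×2 table:
    N·(max(|ad − bc| − N/2, 0))² / [(a+b)(c+d)(a+c)(b+d)]."""
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if any(m == 0 for m in margins):
        raise ZeroMarginError("chi-square undefined: a table margin is zero")
    corrected = max(abs(t.a * t.d - t.b * t.c) - t.n / 2.0, 0.0)
    denom = math.prod(float(m) for m in margins)
    return t.n * corrected * corrected / denom


def fisher_exact_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p by point-probability ordering.

    Conditional on the margins, the exposed-case count follows a
    hypergeometric distribution; the p-value sums the probabilities of all
    tables at most as probable as the observed one (relative tolerance
    :data:`FISHER_RELATIVE_TOL`).  A degenerate margin gives p = 1.
    """
    n, big_k, draws = t.n, t.case_total, t.exposed_total
    if big_k == 0 or draws == 0 or big_k == n or draws == n:
        return 1.0
    lo, hi = max(0, draws - (n - big_k)), min(draws, big_k)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, big_k, draws)
    p_obs = pmf[t.a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_RELATIVE_TOL)].sum())
    return min(p, 1.0)


def prr_wald_ci(t: ContingencyTable, level: float = 0.95) -> ConfidenceInterval | None:
    """Wald interval on the log PRR:
    exp(ln PRR ± z·sqrt(1/a − 1/(a+c) + 1/b − 1/(b+d))).

    Not computable when a = 0 or b = 0 (returns ``None``; callers may fall
    back to :func:`exact_or_ci`).
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if t.a == 0 or t.b == 0:
        return None
    point = prr(t)
    z = sps.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1 / t.a - 1 / t.exposed_total + 1 / t.b - 1 / (t.b + t.d))
    return ConfidenceInterval(
        low=point * math.exp(-z * se),
        high=point * math.exp(z * se),
        level=level,
        method="wald-log-prr",
    )


def exact_or_ci(t: ContingencyTable, level: float = 0.95) -> ConfidenceInterval:
    """Exact conditional odds-ratio interval.

    Inverts the tails of the noncentral (Fisher) hypergeometric
    distribution at (1−level)/2 per side, so a = 0 still yields a finite
    upper limit with low = 0.  This is the interval exact conditional
    routines in standard statistics software produce; it bounds the odds
    ratio, which tracks the PRR closely when cases are rare.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if t.case_total < 1:
        raise ZeroMarginError("exact CI undefined: no cases in either arm")
    res = _scipy_odds_ratio(t.as_array(), kind="conditional")
    ci = res.confidence_interval(confidence_level=level)
    return ConfidenceInterval(low=float(ci.low), high=float(ci.high), level=level,
                              method="exact-conditional-or")


def classify_signal(
    t: ContingencyTable,
    prr_value: float,
    chi2_value: float | None,
    criteria: SignalCriteria = SignalCriteria(),
) -> bool:
    """Evans criteria: a ≥ min_cases, PRR ≥ min_prr (``inf`` passes), and
    Yates chi-square ≥ min_chi2."""
    if chi2_value is None:
        return False
    return (
        t.a >= criteria.min_cases
        and prr_value >= criteria.min_prr
        and chi2_value >= criteria.min_chi2
    )


def analyze_table(
    t: ContingencyTable,
    criteria: SignalCriteria = SignalCriteria(),
    ci_level: float = 0.95,
) -> DisproportionalityResult:
    """Compute every statistic for one table.

    The Wald log-PRR interval is reported when computable (a > 0 and
    b > 0); the exact conditional odds-ratio interval is computed alongside
    whenever any case exists.  Statistics undefined on degenerate margins
    are reported as ``None``/``nan`` rather than erroring the run.
    """
    try:
        prr_value = prr(t)
    except ZeroMarginError:
        prr_value = math.nan
    try:
        chi2_value: float | None = chi2_yates(t)
    except ZeroMarginError:
        chi2_value = None
    fisher_p = fisher_exact_two_sided(t)
    ci = prr_wald_ci(t, ci_level)
    ci_exact = exact_or_ci(t, ci_level) if t.case_total >= 1 else None
    signal = (
        not math.isnan(prr_value)
        and classify_signal(t, prr_value, chi2_value, criteria)
    )
    return DisproportionalityResult(
        table=t,
        prr=prr_value,
        chi2_yates=chi2_value,
        fisher_p=fisher_p,
        ci=ci,
        ci_exact=ci_exact,
        signal=signal,
    )


def format_prr(value: float) -> str:
    """Display rounding for PRR: nearest integer (half away from zero), the
    convention published disproportionality tables use; inf stays 'inf'."""
    if math.isnan(value):
        return "-"
    if math.isinf(value):
        return "inf"
    return str(int(math.floor(value + 0.5)))


def format_chi2(value: float | None) -> str:
    """Display rounding for chi-square: one decimal."""
    if value is None:
        return "-"
    return f"{value:.1f}"
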