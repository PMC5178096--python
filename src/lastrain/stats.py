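"""Two-group cohort statistics.

The battery used on the cohort tables: Shapiro–Wilk-gated two-group
comparison (independent-samples t test when both groups look normal,
Mann–Whitney U otherwise), Pearson correlation, intra-observer ICC, and
percent-change summaries between group means. p-values are reported raw —
no multiple-testing correction is applied, and that should be kept in mind
when reading the comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientSampleError, InvalidInputError

ALPHA_NORMALITY = 0.05
ALPHA_SIGNIFICANCE = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Result of one normality-gated two-group comparison."""

    variable: str
    n_x: int
    n_y: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    test_used: str  # "t-test" | "mann-whitney"
    statistic: float
    p_value: float
    normality_p_x: float
    normality_p_y: float
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p_value: float
    n: int


def compare_groups(
    x,
    y,
    variable: str = "",
    alpha_normality: float = ALPHA_NORMALITY,
    welch: bool = False,
) -> GroupComparison:
    """Compare two independent samples with a Shapiro–Wilk normality gate.

    Both samples normal at ``alpha_normality`` -> two-sided independent
    t test (equal-variance by default; ``welch=True`` for unequal variance).
    Otherwise -> two-sided Mann–Whitney U (exact for small tie-free samples,
    normal approximation with tie/continuity correction beyond n = 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise InsufficientSampleError("each group needs at least 3 observations")

    p_x = float(sps.shapiro(x).pvalue)
    p_y = float(sps.shapiro(y).pvalue)
    if p_x > alpha_normality and p_y > alpha_normality:
        res = sps.ttest_ind(x, y, equal_var=not welch)
        test_used = "t-test"
    else:
        small = len(x) <= 8 and len(y) <= 8
        no_ties = np.unique(np.concatenate([x, y])).size == len(x) + len(y)
        method = "exact" if (small and no_ties) else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        test_used = "mann-whitney"
    p = float(res.pvalue)
    return GroupComparison(
        variable=variable,
        n_x=len(x),
        n_y=len(y),
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)),
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=p,
        normality_p_x=p_x,
        normality_p_y=p_y,
        significant=p < ALPHA_SIGNIFICANCE,
    )


def correlate(x, y, var_x: str = "", var_y: str = "") -> CorrelationResult:
    """Pearson correlation with the two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InvalidInputError("samples must have equal length")
    if len(x) < 3:
        raise InsufficientSampleError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("undefined correlation: zero variance")
    res = sps.pearsonr(x, y)
    return CorrelationResult(var_x=var_x, var_y=var_y, r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def icc_intraobserver(ratings_a, ratings_b, form: str = "icc2") -> float:
    """Single-measure intraclass correlation between two repeated readings.

    ``form='icc2'`` (default): two-way random/mixed, absolute agreement,
    ICC(2,1). ``form='icc3'``: two-way mixed, consistency, ICC(3,1). Computed
    from the two-way ANOVA mean squares of the n-subjects x 2-raters table:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if len(a) != len(b):
        raise InvalidInputError("the two reading vectors must have equal length")
    n = len(a)
    if n < 3:
        raise InsufficientSampleError("ICC needs at least 3 subjects")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0 and mse == 0:
        raise InvalidInputError("undefined ICC: degenerate (constant) ratings")
    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise InvalidInputError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise InvalidInputError("undefined ICC: zero denominator")
    return float((msr - mse) / denom)


def percent_change(reference: float, comparison: float) -> float:
    """(comparison - reference) / reference x 100; positive = increase."""
    if reference == 0:
        raise InvalidInputError("percent change undefined for zero reference")
    return (comparison - reference) / reference * 100.0
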