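"""Statistical layer: growth, t-tests, correlations, cohort summaries.

All tests are two-tailed and uncorrected.  Half-life cohorts may contain
"no decay" entries (``None``): inside the one-sample t-test these are
replaced by a fixed surrogate (100 min by default, following the convention
of treating a non-decaying transcript as very long-lived for the test),
while medians, ranges and fractions simply exclude them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySummaryError, NoGrowthError, UndefinedCorrelationError, ValidationError

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "RegressionResult",
    "GroupSummary",
    "generation_time",
    "one_sample_ttest",
    "pearson",
    "mann_whitney",
    "cv_vs_mean_regression",
    "summarize_halflives",
]


@dataclass(frozen=True)
class TTestResult:
    n: int
    mean: float
    t_statistic: float
    p_value: float
    mu: float


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    n: int
    r: float
    p_value: float
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    min: float
    max: float
    mean: float
    cv: float
    threshold: float
    fraction_below: float


def generation_time(t: float, n0: float, n: float) -> float:
    """Doubling time G = t / ((log N − log N0) / log 2) over a growth segment.

    ``t`` spans the exponential phase (hours), ``n0``/``n`` are cell
    abundances at its start and end.
    """
    if t <= 0:
        raise ValidationError("elapsed time must be positive")
    if n0 <= 0:
        raise ValidationError("initial abundance must be positive")
    if n <= n0:
        raise NoGrowthError(f"no growth: N={n:g} <= N0={n0:g}")
    return t / ((math.log(n) - math.log(n0)) / math.log(2))


def one_sample_ttest(
    values: Sequence[float | None],
    mu: float,
    no_decay_replacement: float = 100.0,
    exclusions: Sequence[int] = (),
) -> TTestResult:
    """Two-tailed one-sample t-test of half-lives against a reference.

    ``None`` entries (no decay) are replaced by ``no_decay_replacement``
    minutes before testing; ``exclusions`` are indices into ``values`` left
    out entirely (e.g. a flagged outlier gene).  If every retained value
    equals ``mu`` the statistic is 0 and p is exactly 1.
    """
    kept = [
        no_decay_replacement if v is None else float(v)
        for i, v in enumerate(values)
        if i not in set(exclusions)
    ]
    if len(kept) < 2:
        raise ValidationError("need >= 2 values after exclusions")
    arr = np.asarray(kept)
    if np.all(arr == mu):
        return TTestResult(n=len(arr), mean=float(mu), t_statistic=0.0, p_value=1.0, mu=mu)
    res = stats.ttest_1samp(arr, popmean=mu)
    return TTestResult(
        n=len(arr),
        mean=float(arr.mean()),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mu=mu,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return CorrelationResult(n=len(x), r=float(res.statistic), p_value=float(res.pvalue))


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-tailed Mann–Whitney U p-value.

    Exact null distribution for small samples (n <= 20 each, no ties),
    normal approximation with tie correction otherwise; ties are mid-ranked.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    small = max(len(a), len(b)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def cv_vs_mean_regression(
    halflife_matrix: pd.DataFrame,
) -> tuple[RegressionResult, pd.DataFrame]:
    """Relate variability to magnitude of half-lives across functional groups.

    ``halflife_matrix`` holds half-lives (minutes) with COG subcategories as
    rows and taxonomic classes as columns; missing values are skipped.  Per
    subcategory the mean and coefficient of variation (SD/mean across
    classes) are computed, then the Pearson correlation and OLS line of CV
    on mean, with a 95% CI on the slope.  Subcategories with fewer than two
    class values are dropped with a warning.
    """
    rows = {}
    for subcat, row in halflife_matrix.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"subcategory {subcat!r} has < 2 class values; dropped",
                          stacklevel=2)
            continue
        mean = vals.mean()
        rows[subcat] = {"mean": mean, "cv": vals.std(ddof=1) / mean}
    per_subcat = pd.DataFrame.from_dict(rows, orient="index")
    if len(per_subcat) < 3:
        raise ValidationError("need >= 3 subcategories with >= 2 class values")
    corr = pearson(per_subcat["mean"], per_subcat["cv"])  # may raise UndefinedCorrelation
    reg = stats.linregress(per_subcat["mean"], per_subcat["cv"])
    tcrit = stats.t.ppf(0.975, len(per_subcat) - 2)
    ci = (reg.slope - tcrit * reg.stderr, reg.slope + tcrit * reg.stderr)
    result = RegressionResult(
        n=corr.n,
        r=corr.r,
        p_value=corr.p_value,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        slope_ci95=(float(ci[0]), float(ci[1])),
    )
    return result, per_subcat


def summarize_halflives(
    halflives: Sequence[float | None], threshold: float = 10.0
) -> GroupSummary:
    """Cohort summary of half-lives: median, range, mean, CV, fraction below.

    ``None`` entries (no decay) are excluded — they have no numeric
    half-life.  ``fraction_below`` is the fraction strictly below
    ``threshold`` minutes among the numeric values.
    """
    vals = np.asarray([v for v in halflives if v is not None], dtype=float)
    if len(vals) == 0:
        raise EmptySummaryError("no numeric half-lives to summarize")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return GroupSummary(
        n=len(vals),
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        mean=mean,
        cv=sd / mean if mean > 0 else 0.0,
        threshold=threshold,
        fraction_below=float(np.mean(vals < threshold)),
    )
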