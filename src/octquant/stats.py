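"""Longitudinal statistics: time series, group tests, trend fits.

Per-eye metrics (VIT/RPE ratio, total and mean aggregate area, ILM-RNFL
thickness) are assembled into per-week group series; the group comparisons
mirror the published analysis: Kolmogorov-Smirnov to assess distribution,
Mann-Whitney U between cohorts, paired Wilcoxon within eyes over time, all
two-sided at alpha = 0.05 with no multiple-testing correction.  Trends are
fitted by ordinary least squares, either linear or logarithmic
(y = a ln x + b), and drug-level correlation reports the OLS fit plus
Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from .errors import DegenerateInputError
from .io import EyeTimepointResult

ALPHA = 0.05

#: metric name -> EyeTimepointResult attribute
METRICS = {
    "vit_rpe_ratio": "vit_rpe_ratio",
    "total_area": "total_area_um2",
    "mean_area": "mean_area_um2",
    "ilm_rnfl_thickness": "ilm_rnfl_thickness_um",
}


@dataclass
class MetricTimeSeries:
    """Per-week group mean / sd / n of one metric."""

    metric_name: str
    weeks: np.ndarray
    values: np.ndarray
    spreads: np.ndarray
    n_per_week: np.ndarray

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError("weeks must be strictly increasing")
        if np.any(np.asarray(self.n_per_week) < 1):
            raise ValueError("each included week needs n >= 1")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    test_name: str
    n1: int
    n2: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class FitResult:
    """OLS fit of a linear or logarithmic trend."""

    model: str            # "linear" | "logarithmic"
    slope: float          # coefficient a (on x, or on ln x)
    intercept: float      # b
    r_squared: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    fit: FitResult
    pearson_r: float
    p_value: float
    n: int


def build_timeseries(
    results: Sequence[EyeTimepointResult],
    metric_name: str,
    group: str,
) -> MetricTimeSeries:
    """Per-week mean/sd/n of one metric over the eyes of one group.

    Weeks with no eyes are omitted; sd is 0 for single-eye weeks.
    """
    if metric_name not in METRICS:
        raise KeyError(f"unknown metric {metric_name!r}; one of {sorted(METRICS)}")
    attr = METRICS[metric_name]
    sel = [r for r in results if r.group == group]
    if not sel:
        raise DegenerateInputError(f"no results for group {group!r}")
    weeks = sorted({r.week for r in sel})
    means, sds, ns = [], [], []
    for w in weeks:
        vals = np.array([getattr(r, attr) for r in sel if r.week == w], dtype=float)
        means.append(vals.mean())
        sds.append(vals.std(ddof=1) if vals.size > 1 else 0.0)
        ns.append(vals.size)
    return MetricTimeSeries(
        metric_name=metric_name,
        weeks=np.array(weeks, dtype=float),
        values=np.array(means),
        spreads=np.array(sds),
        n_per_week=np.array(ns, dtype=int),
    )


def test_normality(values: Sequence[float]) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with the sample's mean and standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateInputError(f"need n >= 3, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant sample: normality test undefined")
    res = scipy.stats.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        test_name="kolmogorov_smirnov", n1=x.size,
    )


def compare_cohorts(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test between two cohorts.

    Exact p-value when n1 + n2 <= 12 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("both cohorts must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        test_name="mann_whitney_u", n1=x.size, n2=y.size,
    )


def paired_change(
    before: Sequence[float], after: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Paired Wilcoxon signed-rank test of within-eye change.

    Zero differences are dropped (Wilcoxon convention); the p-value is
    exact for n <= 15 untied differences, the normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.size != y.size:
        raise DegenerateInputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise DegenerateInputError("empty samples")
    d = y - x
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateInputError("all differences are zero")
    ranks_tied = np.unique(np.abs(d)).size != d.size
    method = "exact" if (d.size <= 15 and not ranks_tied) else "approx"
    res = scipy.stats.wilcoxon(
        d, alternative=alternative, method=method,
        correction=(method == "approx"),
    )
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        test_name="wilcoxon_signed_rank", n1=int(d.size),
    )


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    ss_res = float(np.sum((y - pred) ** 2))
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def fit_linear_trend(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Ordinary least-squares line ``y = slope * x + intercept`` with R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise DegenerateInputError("need >= 3 matched points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in x")
    if np.ptp(y) == 0:
        return FitResult("linear", 0.0, float(y[0]), 0.0, x.size)
    slope, intercept = np.polyfit(x, y, 1)
    r2 = _r_squared(y, slope * x + intercept)
    return FitResult("linear", float(slope), float(intercept), r2, x.size)


def fit_log_curve(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """Least-squares logarithmic curve ``y = a ln(x) + b`` with R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise DegenerateInputError("need >= 3 matched points")
    if np.any(x <= 0):
        raise DegenerateInputError("logarithmic fit requires all x > 0")
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise DegenerateInputError("zero variance in ln(x)")
    if np.ptp(y) == 0:
        return FitResult("logarithmic", 0.0, float(y[0]), 0.0, x.size)
    a, b = np.polyfit(lx, y, 1)
    r2 = _r_squared(y, a * lx + b)
    return FitResult("logarithmic", float(a), float(b), r2, x.size)


def correlate_metric_drug(
    metric: Sequence[float], drug: Sequence[float]
) -> CorrelationResult:
    """OLS of a per-week metric on matched per-week drug levels (ng/mL),
    plus Pearson's r.  Requires >= 3 matched weeks."""
    m = np.asarray(metric, dtype=float)
    d = np.asarray(drug, dtype=float)
    if m.size < 3 or d.size != m.size:
        raise DegenerateInputError("need >= 3 matched weeks")
    fit = fit_linear_trend(d, m)
    r, p = scipy.stats.pearsonr(d, m)
    return CorrelationResult(fit=fit, pearson_r=float(r), p_value=float(p), n=m.size)
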