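"""Group-comparison statistics: Welch's t-test, percent differences,
control-normalized values, and boxplot summaries.

Conventions follow common practice for per-embryo measurements: groups are
compared pairwise against a reference (control) group with Welch's unequal-
variance t-test; effect sizes are differences between group *means*
expressed as a percentage of the reference mean; boxplots use linear-
interpolation quartiles and 1.5·IQR whiskers.  No multiple-testing
correction is applied — p-values are raw pairwise values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSample", "BoxplotStats", "ComparisonResult", "welch_t",
           "percent_difference", "boxplot_stats", "compare_groups"]


@dataclass(frozen=True)
class GroupSample:
    """One experimental group: a label plus per-primordium measurements."""

    group: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise ValueError("values must be a non-empty 1D sequence")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BoxplotStats:
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise comparison table plus control-normalized values."""

    reference: str
    table: pd.DataFrame
    normalized: dict = field(default_factory=dict)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with t = (mean_a − mean_b)/√(s²_a/n_a + s²_b/n_b),
    Welch–Satterthwaite degrees of freedom, and a two-sided p-value.  Two
    zero-variance groups with equal means return (0, n_a+n_b−2, 1) by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both groups have zero variance with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def percent_difference(a, b) -> float:
    """Difference of means, mean_b − mean_a, as a percent of the reference
    (first) group's mean."""
    ma = float(np.mean(a))
    if ma == 0:
        raise ValueError("reference mean is zero")
    return 100.0 * (float(np.mean(b)) - ma) / ma


def boxplot_stats(values) -> BoxplotStats:
    """Median, linear-interpolation quartiles, 1.5·IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotStats(
        n=int(v.size), mean=float(v.mean()), median=float(med),
        q1=float(q1), q3=float(q3),
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
        outliers=np.sort(outliers),
    )


def compare_groups(
    samples: Sequence[GroupSample], reference: str
) -> ComparisonResult:
    """Compare every group to the reference group.

    For each group the result table carries n, mean, the boxplot summary,
    the percent difference of means relative to the reference, and the
    Welch test against the reference.  Normalized values (value / reference
    mean) are returned per group; the reference normalizes to mean 1.0.
    """
    by_label = {s.group: s for s in samples}
    if reference not in by_label:
        raise ValueError(f"unknown reference group {reference!r}")
    ref = by_label[reference]
    ref_mean = float(ref.values.mean())
    rows = []
    normalized = {}
    for s in samples:
        bs = boxplot_stats(s.values)
        if s.group == reference:
            t, df, p = 0.0, float("nan"), 1.0
            pct = 0.0
        else:
            t, df, p = welch_t(ref.values, s.values)
            pct = percent_difference(ref.values, s.values)
        normalized[s.group] = s.values / ref_mean if ref_mean != 0 else s.values
        rows.append({
            "group": s.group, "n": bs.n, "mean": bs.mean,
            "median": bs.median, "q1": bs.q1, "q3": bs.q3,
            "whisker_lo": bs.whisker_lo, "whisker_hi": bs.whisker_hi,
            "n_outliers": len(bs.outliers),
            "percent_difference": pct, "welch_t": t, "welch_df": df,
            "p_value": p,
            "normalized_mean": bs.mean / ref_mean if ref_mean != 0 else np.nan,
        })
    table = pd.DataFrame(rows).set_index("group")
    return ComparisonResult(reference=reference, table=table,
                            normalized=normalized)
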