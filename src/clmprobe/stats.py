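"""Statistical comparison and summary statistics for reproduction counts.

The masked-vs-control comparison uses the two-sided Mann-Whitney U test:
exact null distribution when both samples are small (n1+n2 <= 12) and free
of ties, otherwise the normal approximation with midrank tie correction and
continuity correction. Significance labels follow the conventional star
thresholds: ns (p > 0.05), * (p <= 0.05), ** (p <= 0.01), *** (p <= 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 12  # switchover: exact enumeration below, normal approximation above


def significance_label(p: float) -> str:
    if p > 0.05:
        return "ns"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    return "***"


@dataclass(frozen=True)
class StatTestResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "asymptotic"

    @property
    def label(self) -> str:
        return significance_label(self.p_value)


def mann_whitney_u(x, y) -> StatTestResult:
    """Two-sided Mann-Whitney U test with rank-sum U and midrank ties.

    The exact branch (used when n1+n2 <= 12 and there are no ties across
    the pooled sample) enumerates the permutation null; larger or tied
    samples use the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= EXACT_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return StatTestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), x.size, y.size, method
    )


def summarize_curve(per_repeat_curves, grid=None) -> pd.DataFrame:
    """Pointwise mean and sample standard deviation over repeated curves.

    All curves must share the same step grid. With a single repeat the
    standard deviation is reported as missing (NaN), not zero.
    """
    curves = [np.asarray(c, dtype=float) for c in per_repeat_curves]
    if not curves:
        raise ValueError("no curves given")
    n_steps = curves[0].shape[0]
    if any(c.shape[0] != n_steps for c in curves):
        raise ValueError("curves have mismatched step grids")
    stacked = np.vstack(curves)
    mean = stacked.mean(axis=0)
    sd = (
        stacked.std(axis=0, ddof=1)
        if len(curves) > 1
        else np.full(n_steps, np.nan)
    )
    out = pd.DataFrame({"mean": mean, "sd": sd})
    if grid is not None:
        grid = np.asarray(grid)
        if grid.shape[0] != n_steps:
            raise ValueError("grid length mismatch")
        out.insert(0, "n_residues_randomized", grid)
    return out


@dataclass(frozen=True)
class BoxplotSummary:
    """Quartiles, 1.5-IQR whiskers clipped to data, and outliers."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_stats(values) -> BoxplotSummary:
    """Boxplot summary with linear-interpolation quartiles.

    Whiskers sit at the most extreme data points within 1.5 interquartile
    ranges of the quartiles; points beyond are listed as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= low_fence) & (v <= high_fence)]
    outliers = tuple(sorted(v[(v < low_fence) | (v > high_fence)]))
    return BoxplotSummary(
        float(q1),
        float(med),
        float(q3),
        float(inside.min()),
        float(inside.max()),
        outliers,
    )
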