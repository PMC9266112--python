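"""Nonparametric trend machinery: Theil-Sen slope, Mann-Kendall test,
and the comparison of day-count distributions between two periods.

The Theil-Sen estimator is the median of all pairwise slopes
``(x_j - x_i) / (j - i)`` over ``i < j`` -- robust to outliers and exact
for linear series.  The Mann-Kendall test standardises the rank statistic
``S = sum_{i<j} sign(x_j - x_i)`` with the tie-corrected variance
``Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18`` and a continuity
correction, ``z = (S - sign(S)) / sqrt(Var(S))``.  Two-sided significance
tiers use the standard normal quantiles 1.645 / 1.960 / 2.576 for the
90 / 95 / 99% confidence levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrendResult",
    "theil_sen_slope",
    "mann_kendall_z",
    "trend",
    "period_distribution",
    "SIGNIFICANCE_THRESHOLDS",
]

#: (z threshold, confidence level %) in increasing order.
SIGNIFICANCE_THRESHOLDS = ((1.645, 90), (1.960, 95), (2.576, 99))


@dataclass(frozen=True)
class TrendResult:
    """Trend of one yearly series: slope, MK statistic and significance."""

    beta: float
    z: float
    s: int
    var_s: float
    #: 0 (not significant), 90, 95 or 99
    significance_tier: int


def _tier(z: float, thresholds=SIGNIFICANCE_THRESHOLDS) -> int:
    tier = 0
    for thr, level in thresholds:
        if abs(z) >= thr:
            tier = level
    return tier


def theil_sen_slope(series, times=None) -> float:
    """Median of all pairwise slopes (units of ``series`` per time step)."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a slope")
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, float)
    if t.shape != x.shape:
        raise ValueError("times must align with series")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time indices must be strictly increasing")
    i, j = np.triu_indices(x.size, k=1)
    slopes = (x[j] - x[i]) / (t[j] - t[i])
    return float(np.median(slopes))


def mann_kendall_z(series, min_length: int = 8, continuity_correction: bool = True,
                   tie_correction: bool = True) -> TrendResult:
    """Mann-Kendall trend test on a yearly series.

    Returns the full :class:`TrendResult` (the Theil-Sen slope is computed
    alongside so one call yields both the slope and its significance).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < min_length:
        raise ValueError(f"series too short for the normal approximation: "
                         f"{n} < {min_length}")
    i, j = np.triu_indices(n, k=1)
    s = int(np.sign(x[j] - x[i]).sum())

    var = n * (n - 1) * (2 * n + 5) / 18.0
    if tie_correction:
        _, counts = np.unique(x, return_counts=True)
        ties = counts[counts > 1]
        var -= np.sum(ties * (ties - 1) * (2 * ties + 5)) / 18.0

    if s == 0 or var == 0:
        z = 0.0
    elif continuity_correction:
        z = (s - np.sign(s)) / np.sqrt(var)
    else:
        z = s / np.sqrt(var)

    return TrendResult(
        beta=theil_sen_slope(x), z=float(z), s=s, var_s=float(var),
        significance_tier=_tier(z),
    )


#: alias: the one-call trend analysis of a yearly series
trend = mann_kendall_z


def period_distribution(day_counts_by_year, period_a, period_b, smooth: bool = True):
    """Compare the distribution of annual values between two year ranges.

    Parameters
    ----------
    day_counts_by_year : DataFrame
        Indexed by year, one column per category (or any annual metric).
    period_a, period_b : (first_year, last_year)
        Inclusive, disjoint year ranges.
    smooth : bool
        Attach a Gaussian-KDE density per period where the data admit one
        (more than one distinct value); degenerate samples get ``None``.

    Returns
    -------
    dict mapping column -> dict with keys ``mean_a``, ``mean_b``,
    ``mean_shift`` (b minus a), ``values_a``, ``values_b``, ``density_a``,
    ``density_b``.
    """
    a0, a1 = period_a
    b0, b1 = period_b
    if a0 > a1 or b0 > b1:
        raise ValueError("period bounds must be (first_year, last_year)")
    if not (a1 < b0 or b1 < a0):
        raise ValueError(f"periods overlap: {period_a} vs {period_b}")
    years = np.asarray(day_counts_by_year.index)
    in_a = (years >= a0) & (years <= a1)
    in_b = (years >= b0) & (years <= b1)
    if not in_a.any() or not in_b.any():
        raise ValueError("each period must contain at least one year of data")

    def _kde(vals):
        if not smooth or np.unique(vals).size < 2 or vals.size < 3:
            return None
        return stats.gaussian_kde(vals)

    report = {}
    for col in day_counts_by_year.columns:
        va = day_counts_by_year.loc[in_a, col].to_numpy(dtype=float)
        vb = day_counts_by_year.loc[in_b, col].to_numpy(dtype=float)
        report[col] = {
            "mean_a": float(va.mean()),
            "mean_b": float(vb.mean()),
            "mean_shift": float(vb.mean() - va.mean()),
            "values_a": va,
            "values_b": vb,
            "density_a": _kde(va),
            "density_b": _kde(vb),
        }
    return report
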