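"""Kill-curve and growth-rate statistics.

Relative survival is the ratio of colony-forming units after a stated period
of thymidine starvation to the count at its start; strain comparisons use a
Welch (unequal-variance) t-test on log10 relative survival, matching the
log-scale on which kill curves are read.  Doubling rates come from the
maximal-slope window of a log-linear fit to OD600 time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .flow import significance_stars  # same star convention across figures

__all__ = [
    "relative_survival",
    "summarize_survival",
    "welch_test",
    "doubling_rate",
    "GrowthFit",
    "significance_stars",
]


def relative_survival(cfu_t, cfu_0, detection_limit: float = 1.0):
    """Relative survival cfu_t / cfu_0 and its log10.

    ``cfu_0`` must be positive.  A zero ``cfu_t`` has no finite log ratio and
    is reported censored at ``detection_limit`` CFU (log10 of
    detection_limit/cfu_0), with the ``censored`` flag set.

    Returns (ratio, log10_ratio, censored) as scalars or arrays.
    """
    cfu_t = np.asarray(cfu_t, dtype=float)
    cfu_0 = np.asarray(cfu_0, dtype=float)
    if (cfu_0 <= 0).any():
        raise ValueError("cfu_0 must be positive")
    if (cfu_t < 0).any():
        raise ValueError("cfu_t must be non-negative")
    ratio = cfu_t / cfu_0
    censored = cfu_t == 0
    safe = np.where(censored, detection_limit / cfu_0, ratio)
    log10_ratio = np.log10(safe)
    if ratio.ndim == 0:
        return float(ratio), float(log10_ratio), bool(censored)
    return ratio, log10_ratio, censored


def summarize_survival(log10_ratios) -> dict:
    """Mean, SD and SEM of replicate log10 relative survivals."""
    x = np.asarray(log10_ratios, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no replicates")
    sd = float(x.std(ddof=1)) if n > 1 else np.nan
    return {
        "n": n,
        "mean": float(x.mean()),
        "sd": sd,
        "sem": sd / np.sqrt(n) if n > 1 else np.nan,
    }


def welch_test(group_a, group_b) -> float:
    """Two-sided Welch t-test p-value between replicate groups.

    Intended for log10 relative survivals.  Degenerate zero-variance groups
    with equal means give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


@dataclass
class GrowthFit:
    doublings_per_hour: float
    window: tuple[float, float]   # time span (h) of the fitted exponential window
    r_squared: float
    n_points: int


def doubling_rate(
    time_h,
    od600,
    window: int = 5,
    blank: float | None = None,
    min_r2: float = 0.98,
) -> GrowthFit:
    """Doublings per hour from the steepest log-linear window of an OD series.

    The first-timepoint OD is subtracted as blank (override with ``blank``),
    non-positive values are masked, and a sliding window of ``window`` points
    is fit by least squares on log2(OD); the window with the maximal slope is
    reported.  If no window reaches R^2 >= ``min_r2`` the best-R^2 window is
    returned with a warning.
    """
    import warnings

    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if len(t) != len(od):
        raise ValueError("time and OD series differ in length")
    blank = od[0] if blank is None else blank
    y = od - blank
    mask = y > 0
    t, y = t[mask], y[mask]
    if len(t) < max(window, 6):
        raise ValueError(f"need >= {max(window, 6)} points above blank, have {len(t)}")
    log2_od = np.log2(y)

    best = None  # (slope, r2, t_start, t_end)
    for i in range(len(t) - window + 1):
        tt, yy = t[i : i + window], log2_od[i : i + window]
        slope, intercept, r, _, _ = stats.linregress(tt, yy)
        r2 = r * r
        cand = (slope, r2, tt[0], tt[-1])
        if r2 >= min_r2:
            if best is None or best[1] < min_r2 or cand[0] > best[0]:
                best = cand
        elif best is None or (best[1] < min_r2 and r2 > best[1]):
            best = cand
    slope, r2, t0, t1 = best
    if r2 < min_r2:
        warnings.warn(
            f"no {window}-point window reached R^2 >= {min_r2}; "
            f"best window R^2 = {r2:.3f}",
            stacklevel=2,
        )
    return GrowthFit(
        doublings_per_hour=float(slope),
        window=(float(t0), float(t1)),
        r_squared=float(r2),
        n_points=window,
    )
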