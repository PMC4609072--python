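"""Statistical layer: score calibration, dose-response fits, group summaries.

Three small estimators used throughout the treatment analysis:

* a piecewise linear visual-vs-auto score calibration with a fixed
  breakpoint -- the low segment is a least-squares line through the origin
  (visual counting tracks true counts), the high segment an ordinary line
  (visual counting saturates); the segments are fitted independently and
  continuity is deliberately not enforced;
* ordinary least-squares dose-response lines with the zero-crossing
  pressure ``x0 = -intercept/slope`` as a threshold estimate;
* boxplot five-number summaries with the 1.5 IQR outlier rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PiecewiseFit",
    "DoseResponseFit",
    "BoxplotSummary",
    "piecewise_fit",
    "fit_zero_crossing",
    "boxplot_summary",
]


@dataclass(frozen=True)
class PiecewiseFit:
    """Two independent segments split at a fixed breakpoint.

    Low segment (x <= breakpoint): ``y = a1 * x`` through the origin.
    High segment (x > breakpoint): ``y = a2 * x + b``.  Coefficients of a
    segment holding fewer than two points are NaN.
    """

    a1: float
    a2: float
    b: float
    breakpoint: float
    r2_low: float
    r2_high: float


@dataclass(frozen=True)
class DoseResponseFit:
    """Ordinary least-squares line with its zero-crossing threshold."""

    slope: float
    intercept: float
    x_zero: float  # -intercept/slope; NaN for a flat line
    r_squared: float

    @property
    def x_zero_display(self) -> float:
        """Zero crossing rounded to one decimal, as conventionally printed."""
        return round(self.x_zero, 1)


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary with 1.5 IQR whiskers and individual outliers."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def piecewise_fit(
    auto_scores,
    visual_scores,
    breakpoint: float = 15_000.0,
) -> PiecewiseFit:
    """Piecewise least-squares calibration of visual against auto scores.

    Points with auto score <= breakpoint form the low segment, fitted as a
    proportional law ``y = a1 x``; the rest form the high segment, fitted
    as ``y = a2 x + b``.  A segment with fewer than two points yields NaN
    coefficients for that segment.
    """
    x = np.asarray(auto_scores, float)
    y = np.asarray(visual_scores, float)
    if x.shape != y.shape:
        raise ValueError("auto and visual scores must have equal length")
    low = x <= breakpoint
    high = ~low

    if low.sum() >= 2:
        a1 = float((x[low] @ y[low]) / (x[low] @ x[low]))
        r2_low = _r_squared(y[low], a1 * x[low])
    else:
        a1, r2_low = math.nan, math.nan

    if high.sum() >= 2:
        a2, b = (float(v) for v in np.polyfit(x[high], y[high], 1))
        r2_high = _r_squared(y[high], a2 * x[high] + b)
    else:
        a2, b, r2_high = math.nan, math.nan, math.nan

    return PiecewiseFit(a1, a2, b, breakpoint, r2_low, r2_high)


def fit_zero_crossing(x, y) -> DoseResponseFit:
    """Least-squares dose-response line and its x-intercept.

    ``x_zero = -intercept/slope`` estimates the pressure at which the
    response extrapolates to zero; it is NaN when the fitted slope is zero.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 2:
        raise ValueError("at least two distinct x values are required")
    # explicit normal equations: exactly zero slope for constant responses
    xc = x - x.mean()
    yc = y - y.mean()
    slope = float((xc @ yc) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    x_zero = -intercept / slope if slope != 0 else math.nan
    return DoseResponseFit(slope, intercept, x_zero, _r_squared(y, slope * x + intercept))


def boxplot_summary(values) -> BoxplotSummary:
    """Quartiles, 1.5 IQR whiskers and outliers of a sample.

    Quartiles use linear interpolation between order statistics.  Outliers
    are exactly the points above ``q3 + 1.5 (q3 - q1)`` or below
    ``q1 - 1.5 (q3 - q1)``; whiskers extend to the most extreme points that
    are not outliers.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("boxplot summary of an empty sample is undefined")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    is_out = (v > hi_fence) | (v < lo_fence)
    inliers = v[~is_out]
    return BoxplotSummary(
        float(med),
        float(q1),
        float(q3),
        float(inliers.min()),
        float(inliers.max()),
        np.sort(v[is_out]),
    )
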