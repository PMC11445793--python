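"""Macro-level trendline fit and the emotion gradient.

Dream charts typically oscillate between peaks and troughs, so the
macro-level direction of emotional change is summarized by a least-squares
polynomial trendline (default degree 2).  The scalar "emotion gradient" is
the mean slope of the fitted polynomial over the chart's domain,

    gradient = (p(x_W) - p(x_1)) / (x_W - x_1),

which equals the line's slope for a degree-1 fit, is antisymmetric under
negating the chart, and is positive when the dream trends toward positive
emotion.  The fit also reports r-squared as a goodness-of-fit diagnostic
and an eligibility flag; charts with fewer points than coefficients, or an
r-squared below a configurable floor, are marked ineligible rather than
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .windowing import DreamChart

__all__ = ["TrendFit", "fit_trend", "emotion_gradient"]


@dataclass(frozen=True)
class TrendFit:
    """A polynomial trendline fitted to one dream chart.

    ``coefficients`` are ordered from the constant term upward;
    ``linear_slope`` is the slope of a separate degree-1 fit, reported for
    comparison with the polynomial-based gradient.
    """

    report_id: str
    degree: int
    coefficients: tuple[float, ...]
    r_squared: float
    emotion_gradient: float
    linear_slope: float
    eligible: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("need degree + 1 coefficients")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if not np.isfinite(self.emotion_gradient):
            raise ValueError("emotion_gradient must be finite")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return npoly.polyval(np.asarray(x, dtype=float), np.array(self.coefficients))


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a constant chart is fit exactly by its own mean; detect constancy up to
    # float representation wobble rather than by ss_tot == 0 exactly
    if ss_tot == 0.0 or np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        return 1.0
    ss_res = float(np.sum((y - fitted) ** 2))
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def emotion_gradient(coefficients: np.ndarray | tuple, chart: DreamChart) -> float:
    """Mean slope of the fitted polynomial over the chart's domain.

    Zero for a single-window chart, where no direction is defined.
    """
    if chart.n_windows < 2:
        return 0.0
    coeffs = np.asarray(coefficients, dtype=float)
    x1, xw = chart.x[0], chart.x[-1]
    return float((npoly.polyval(xw, coeffs) - npoly.polyval(x1, coeffs)) / (xw - x1))


def fit_trend(chart: DreamChart, degree: int = 2, r2_floor: float = 0.0) -> TrendFit:
    """Fit a least-squares polynomial trendline of the given degree.

    If the chart has fewer than degree + 1 points the fit degenerates to the
    highest degree the data support and is flagged ineligible; a
    single-window chart yields a constant fit with gradient 0.  ``r2_floor``
    marks fits below the given r-squared as ineligible (0 = keep all).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    x, y = chart.x, chart.y
    W = chart.n_windows

    if W < 2:
        coeffs = np.zeros(degree + 1)
        coeffs[0] = y[0]
        return TrendFit(
            report_id=chart.report_id,
            degree=degree,
            coefficients=tuple(coeffs),
            r_squared=1.0,
            emotion_gradient=0.0,
            linear_slope=0.0,
            eligible=False,
        )

    eff_degree = min(degree, W - 1)
    coeffs = npoly.polyfit(x, y, eff_degree)
    coeffs = np.concatenate([coeffs, np.zeros(degree + 1 - len(coeffs))])
    r2 = _r_squared(y, npoly.polyval(x, coeffs))
    grad = emotion_gradient(coeffs, chart)
    linear_slope = float(npoly.polyfit(x, y, 1)[1])
    eligible = (W >= degree + 1) and (r2 >= r2_floor)
    return TrendFit(
        report_id=chart.report_id,
        degree=degree,
        coefficients=tuple(coeffs),
        r_squared=r2,
        emotion_gradient=grad,
        linear_slope=linear_slope,
        eligible=eligible,
    )
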