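"""Trilinear non-parametric model of a contrast-enhancement curve.

The model separates a time-intensity curve into three phases:

* a **non-enhancement phase** — a static (constant) line at the baseline
  attenuation before contrast arrival;
* an **upslope phase** — a straight line capturing the first-pass
  enhancement, fitted over a small window of samples around the steepest
  part of the curve;
* a **washout phase** — a straight line over everything after the window.

Two derived quantities are the biomarkers: the *enhancement slope* (HU/s,
the slope of the upslope line) and the *peak enhancement* (HU, the height
of the upslope/washout intersection above the baseline line).  The onset of
enhancement is the intersection of the baseline and upslope lines.

Fitting is a two-step procedure: a cubic smoothing spline locates the time
zone of the first upslope via the maximum of its derivative, then ordinary
least squares fits the three lines on the phase partition induced by a
five-sample window centred on that maximum.  The window deliberately covers
only the first part of the rise so that recirculation of contrast does not
contaminate the slope estimate; the procedure is a heuristic localisation,
not a global least-squares optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .curve import TimeIntensityCurve
from .errors import (
    DegenerateGeometryError,
    InsufficientPhaseSupportError,
    InsufficientSamplesError,
    NonEnhancingCurveError,
    StageError,
)

MIN_PHASE_POINTS = 2  # samples required on each side of the upslope window
MIN_WINDOW = 3


@dataclass(frozen=True)
class SplineSummary:
    """Smoothing-spline view of a curve: smoothed values, analytic first
    derivative at the sample times, and the index of the steepest sample."""

    smoothed_values: np.ndarray
    derivative: np.ndarray
    argmax_derivative_index: int
    smoothing: float


@dataclass(frozen=True)
class TrilinearFit:
    """Fitted three-phase model and its derived perfusion quantities.

    ``peak_enhancement`` is reported relative to the baseline level, i.e.
    the modelled attenuation rise above the static line; by construction it
    equals ``upslope_slope * (peak_time - onset_time)``.
    """

    baseline_level: float
    upslope_slope: float
    upslope_intercept: float
    washout_slope: float
    washout_intercept: float
    onset_time: float
    peak_time: float
    peak_enhancement: float
    rss: float
    window_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.onset_time < self.peak_time:
            raise DegenerateGeometryError(
                f"degenerate geometry: onset {self.onset_time:.3f} s not "
                f"before peak {self.peak_time:.3f} s"
            )

    def predict(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the piecewise-linear model at arbitrary times."""
        t = np.asarray(times, dtype=float)
        up = self.upslope_slope * t + self.upslope_intercept
        wash = self.washout_slope * t + self.washout_intercept
        out = np.where(t < self.onset_time, self.baseline_level,
                       np.where(t < self.peak_time, up, wash))
        return out

    def as_dict(self) -> dict:
        return {
            "baseline_level": self.baseline_level,
            "upslope_slope": self.upslope_slope,
            "upslope_intercept": self.upslope_intercept,
            "washout_slope": self.washout_slope,
            "washout_intercept": self.washout_intercept,
            "onset_time": self.onset_time,
            "peak_time": self.peak_time,
            "peak_enhancement": self.peak_enhancement,
            "rss": self.rss,
            "window_start": self.window_indices[0],
            "window_stop": self.window_indices[-1],
        }


def default_smoothing(times: np.ndarray) -> float:
    """Default roughness penalty for the localisation spline.

    The spline's only job is to locate the upslope zone, so the smoothing
    bandwidth is tied to the sampling density rather than the noise level:
    a penalty of ``2.5 * (mean spacing)^3`` rounds the curve over a kernel
    of the order of one sample spacing, which keeps the derivative maximum at
    the centre of the upslope both for noiseless piecewise-linear curves
    (where a near-interpolating spline would peak next to a kink instead)
    and under measurement noise of a few HU.
    """
    dt = float(np.mean(np.diff(np.asarray(times, dtype=float))))
    return dt ** 3 * 2.5


def fit_spline(curve: TimeIntensityCurve, smoothing: float | None = None
               ) -> SplineSummary:
    """Fit a cubic smoothing spline and locate the steepest sample.

    Parameters
    ----------
    curve : TimeIntensityCurve
    smoothing : float or None
        Non-negative roughness penalty ``lam`` of the penalized smoothing
        spline (knots at every sample).  ``None`` selects a bandwidth of
        the order of the sample spacing (see :func:`default_smoothing`).

    Returns
    -------
    SplineSummary
        Smoothed values, first derivative at the sample times, and the
        index of the maximum derivative (first index on ties).
    """
    if len(curve) < 8:  # redundant with curve invariant; explicit per contract
        raise InsufficientSamplesError(
            f"spline fit requires >= 8 samples, got {len(curve)}"
        )
    if smoothing is None:
        smoothing = default_smoothing(curve.times)
    if smoothing < 0:
        raise ValueError(f"smoothing must be non-negative, got {smoothing}")
    spl = make_smoothing_spline(curve.times, curve.values, lam=smoothing)
    smoothed = spl(curve.times)
    deriv = spl.derivative()(curve.times)
    argmax = int(np.argmax(deriv))  # np.argmax returns first max on ties
    return SplineSummary(smoothed_values=smoothed, derivative=deriv,
                         argmax_derivative_index=argmax,
                         smoothing=float(smoothing))


def select_upslope_window(spline: SplineSummary, curve: TimeIntensityCurve,
                          window_size: int = 5) -> range:
    """Choose the contiguous sample window assigned to the upslope phase.

    The window of ``window_size`` samples is centred on the maximum
    derivative (for the default 5: two before, the argmax, two after).  At
    the curve boundaries it is shifted to preserve its size when possible
    and shrunk (never below 3) otherwise, always keeping the argmax inside
    and at least two samples on each side for the non-enhancement and
    washout phases.
    """
    n = len(curve)
    c = spline.argmax_derivative_index
    if window_size < MIN_WINDOW:
        raise ValueError(f"window_size must be >= {MIN_WINDOW}")
    lo = MIN_PHASE_POINTS            # first admissible window index
    hi = n - 1 - MIN_PHASE_POINTS    # last admissible window index
    if c < lo or c > hi:
        raise InsufficientPhaseSupportError(
            "insufficient phase support: maximum derivative at sample "
            f"{c} leaves fewer than {MIN_PHASE_POINTS} samples in the "
            "non-enhancement or washout phase"
        )
    available = hi - lo + 1
    size = min(window_size, available)
    if size < MIN_WINDOW:
        raise InsufficientPhaseSupportError(
            f"insufficient phase support: only {available} samples "
            f"available for an upslope window (minimum {MIN_WINDOW})"
        )
    start = c - (size - 1) // 2
    start = min(max(start, lo), hi - size + 1)
    return range(start, start + size)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope), float(intercept)


def fit_trilinear(curve: TimeIntensityCurve, window: range,
                  washout_cap: float | None = None) -> TrilinearFit:
    """Least-squares trilinear fit on a given phase partition.

    Samples before ``window`` form the non-enhancement phase (constant
    fit), the window samples the upslope phase, and samples after the
    window the washout phase (straight-line fits).  Onset and peak follow
    from line intersections.

    Parameters
    ----------
    washout_cap : float or None
        If given, washout samples later than this time (s) are excluded
        from the washout line fit and the residual sum; the default uses
        every post-window sample including the late acquisitions.
    """
    t, y = curve.times, curve.values
    w0, w1 = window[0], window[-1]
    if w0 < MIN_PHASE_POINTS or w1 > len(curve) - 1 - MIN_PHASE_POINTS:
        raise InsufficientPhaseSupportError(
            "insufficient phase support: need >= 2 samples before and "
            "after the upslope window"
        )
    pre = slice(0, w0)
    win = slice(w0, w1 + 1)
    post_idx = np.arange(w1 + 1, len(curve))
    if washout_cap is not None:
        post_idx = post_idx[t[post_idx] <= washout_cap]
    if post_idx.size < MIN_PHASE_POINTS:
        raise InsufficientPhaseSupportError(
            "insufficient phase support: washout cap leaves fewer than "
            "2 washout samples"
        )

    baseline = float(np.mean(y[pre]))
    up_slope, up_int = _ols_line(t[win], y[win])
    wo_slope, wo_int = _ols_line(t[post_idx], y[post_idx])

    if up_slope <= 0:
        raise NonEnhancingCurveError(
            f"non-enhancing curve: fitted upslope slope {up_slope:.4g} "
            "HU/s is not positive"
        )
    if up_slope <= wo_slope:
        raise DegenerateGeometryError(
            "degenerate geometry: upslope slope "
            f"{up_slope:.4g} <= washout slope {wo_slope:.4g}"
        )

    onset = (baseline - up_int) / up_slope
    peak_time = (wo_int - up_int) / (up_slope - wo_slope)
    peak_value = up_slope * peak_time + up_int
    rss = (float(np.sum((y[pre] - baseline) ** 2))
           + float(np.sum((y[win] - (up_slope * t[win] + up_int)) ** 2))
           + float(np.sum((y[post_idx] - (wo_slope * t[post_idx] + wo_int)) ** 2)))
    return TrilinearFit(
        baseline_level=baseline,
        upslope_slope=up_slope,
        upslope_intercept=up_int,
        washout_slope=wo_slope,
        washout_intercept=wo_int,
        onset_time=float(onset),
        peak_time=float(peak_time),
        peak_enhancement=float(peak_value - baseline),
        rss=rss,
        window_indices=tuple(window),
    )


def fit_curve(curve: TimeIntensityCurve, smoothing: float | None = None,
              window_size: int = 5, washout_cap: float | None = None
              ) -> TrilinearFit:
    """Full two-step fit: spline localisation then trilinear least squares.

    Component errors are re-raised wrapped in :class:`StageError` with the
    stage (``spline``, ``window`` or ``trilinear``) in the message.
    """
    try:
        summary = fit_spline(curve, smoothing=smoothing)
    except Exception as exc:  # noqa: BLE001 - stage labelling
        raise StageError("spline", exc) from exc
    try:
        window = select_upslope_window(summary, curve, window_size=window_size)
    except Exception as exc:
        raise StageError("window", exc) from exc
    try:
        return fit_trilinear(curve, window, washout_cap=washout_cap)
    except Exception as exc:
        raise StageError("trilinear", exc) from exc


class TrilinearCurveModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator wrapping the trilinear curve fit.

    ``fit(X, y)`` takes acquisition times as a single-column array ``X``
    (seconds) and mean attenuation ``y`` (HU); fitted perfusion quantities
    are exposed as trailing-underscore attributes and ``predict`` evaluates
    the piecewise-linear model.

    Parameters
    ----------
    smoothing : float or None, default None
        Spline smoothing factor; ``None`` auto-selects from the estimated
        noise level.
    window_size : int, default 5
        Number of samples in the upslope window.
    washout_cap : float or None, default None
        Latest time (s) admitted to the washout line fit.

    Attributes
    ----------
    slope_ : float
        Enhancement slope (HU/s).
    peak_enhancement_ : float
        Peak enhancement above baseline (HU).
    baseline_level_, onset_time_, peak_time_, washout_slope_, rss_ : float
    window_indices_ : tuple of int
    result_ : TrilinearFit
        The full fit object.
    """

    def __init__(self, smoothing: float | None = None, window_size: int = 5,
                 washout_cap: float | None = None):
        self.smoothing = smoothing
        self.window_size = window_size
        self.washout_cap = washout_cap

    def _as_curve(self, X, y) -> TimeIntensityCurve:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be a single column of times")
            t = t[:, 0]
        return TimeIntensityCurve(t, np.asarray(y, dtype=float))

    def fit(self, X, y):
        curve = self._as_curve(X, y)
        res = fit_curve(curve, smoothing=self.smoothing,
                        window_size=self.window_size,
                        washout_cap=self.washout_cap)
        self.result_ = res
        self.baseline_level_ = res.baseline_level
        self.slope_ = res.upslope_slope
        self.washout_slope_ = res.washout_slope
        self.onset_time_ = res.onset_time
        self.peak_time_ = res.peak_time
        self.peak_enhancement_ = res.peak_enhancement
        self.rss_ = res.rss
        self.window_indices_ = res.window_indices
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return self.result_.predict(t)
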