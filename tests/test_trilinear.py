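"""Unit and property tests for the trilinear curve model."""

import numpy as np
import pytest

from ctperf import (
    DegenerateGeometryError,
    InsufficientPhaseSupportError,
    InsufficientSamplesError,
    NonEnhancingCurveError,
    StageError,
    TimeIntensityCurve,
    TrilinearCurveModel,
    fit_curve,
    fit_spline,
    fit_trilinear,
    generate_tic,
    select_upslope_window,
)
from ctperf.synthetic import place_onset
from ctperf.trilinear import SplineSummary

from conftest import trilinear_values


# ---------------------------------------------------------------- spline

def test_spline_derivative_of_linear_curve_is_constant():
    t = np.arange(0.0, 40.0, 2.0)
    curve = TimeIntensityCurve(t, 40.0 + 2.0 * t)
    summary = fit_spline(curve)
    assert np.allclose(summary.derivative, 2.0, atol=1e-6)
    # first index wins on (numerical) ties
    assert summary.argmax_derivative_index == int(
        np.argmax(summary.derivative))


def test_spline_argmax_lands_inside_the_upslope(protocol):
    y = trilinear_values(protocol.times, 40.0, 6.0, 2.0, 20.0, -0.2)
    summary = fit_spline(TimeIntensityCurve(protocol.times, y))
    t_star = protocol.times[summary.argmax_derivative_index]
    assert 6.0 <= t_star <= 16.0


def test_spline_argmax_matches_finite_difference_argmax(rng):
    """On 100 random smooth enhancement-like curves (one dominant rise)
    the spline-derivative argmax agrees with the argmax of central finite
    differences of the smoothed values within one index."""
    t = np.arange(0.0, 54.0, 2.0)
    for _ in range(100):
        center = rng.uniform(14.0, 40.0)
        width = rng.uniform(3.0, 8.0)
        amp = rng.uniform(20.0, 60.0)
        y = (40.0 + amp / (1.0 + np.exp(-(t - center) / width))
             + rng.uniform(1.0, 3.0) * np.sin(t / rng.uniform(4.0, 9.0)))
        summary = fit_spline(TimeIntensityCurve(t, y))
        fd = np.gradient(summary.smoothed_values, t)
        # one-sided edge differences are not part of the central-FD oracle
        fd_argmax = 1 + int(np.argmax(fd[1:-1]))
        assert abs(summary.argmax_derivative_index - fd_argmax) <= 1


def test_spline_rejects_short_and_nonfinite_input():
    with pytest.raises(InsufficientSamplesError, match="8"):
        TimeIntensityCurve(np.arange(5.0), np.ones(5))
    with pytest.raises(ValueError, match="finite|gaps"):
        TimeIntensityCurve(np.arange(10.0),
                           np.r_[np.ones(9), np.nan])


# ------------------------------------------------------ window selection

def _summary_with_argmax(n, c):
    deriv = np.zeros(n)
    deriv[c] = 1.0
    return SplineSummary(np.zeros(n), deriv, c, 0.0)


def test_window_centering_two_before_two_after():
    curve = TimeIntensityCurve(np.arange(27.0), np.zeros(27) + 40)
    win = select_upslope_window(_summary_with_argmax(27, 6), curve, 5)
    assert list(win) == [4, 5, 6, 7, 8]


def test_window_near_boundary_raises_insufficient_phase_support():
    curve = TimeIntensityCurve(np.arange(27.0), np.zeros(27) + 40)
    with pytest.raises(InsufficientPhaseSupportError,
                       match="insufficient phase support"):
        select_upslope_window(_summary_with_argmax(27, 1), curve, 5)


@pytest.mark.parametrize("c", range(2, 25))
def test_window_always_contains_argmax_and_is_contiguous(c):
    curve = TimeIntensityCurve(np.arange(27.0), np.zeros(27) + 40)
    win = select_upslope_window(_summary_with_argmax(27, c), curve, 5)
    assert c in win
    assert list(win) == list(range(win.start, win.stop))
    assert win.start >= 2 and win.stop <= 25


def test_window_shrinks_on_short_curves_but_never_below_three():
    curve = TimeIntensityCurve(np.arange(8.0), np.zeros(8) + 40)
    win = select_upslope_window(_summary_with_argmax(8, 4), curve, 5)
    assert 3 <= len(win) <= 5
    assert 4 in win


# --------------------------------------------------------- trilinear fit

def test_exact_trilinear_curve_is_recovered(uniform_grid_curve):
    """A noiseless member of the model family is fitted exactly: slope
    2 HU/s, onset 6 s, peak enhancement 20 HU, zero residual."""
    fit = fit_trilinear(uniform_grid_curve, range(4, 9))
    assert fit.upslope_slope == pytest.approx(2.0, abs=1e-6)
    assert fit.onset_time == pytest.approx(6.0, abs=1e-6)
    assert fit.peak_time == pytest.approx(16.0, abs=1e-6)
    assert fit.peak_enhancement == pytest.approx(20.0, abs=1e-6)
    assert fit.baseline_level == pytest.approx(40.0, abs=1e-6)
    assert fit.rss == pytest.approx(0.0, abs=1e-9)


def test_peak_enhancement_consistency_invariant(uniform_grid_curve):
    fit = fit_trilinear(uniform_grid_curve, range(4, 9))
    expected = fit.upslope_slope * (fit.peak_time - fit.onset_time)
    assert fit.peak_enhancement == pytest.approx(expected, rel=1e-9)


def test_noisy_fit_close_to_exhaustive_partition_oracle(protocol, rng,
                                                        oracle_rss):
    """With moderate noise the heuristic fit's total RSS stays close to
    the best same-window-size partition found by brute force."""
    onset = place_onset(14.0, protocol, washout_ratio=-0.1)
    y0 = trilinear_values(protocol.times, 40.0, onset, 2.0, 28.0, -0.2)
    close = 0
    for _ in range(50):
        y = y0 + rng.normal(0.0, 3.0, y0.size)
        fit = fit_curve(TimeIntensityCurve(protocol.times, y))
        best = oracle_rss(protocol.times, y, window_size=5)
        if fit.rss <= 1.25 * best:
            close += 1
    assert close >= 45


def test_non_enhancing_curve_raises():
    t = np.arange(0.0, 40.0, 2.0)
    curve = TimeIntensityCurve(t, 45.0 - 0.5 * t)
    with pytest.raises(NonEnhancingCurveError, match="non-enhancing"):
        fit_trilinear(curve, range(8, 13))


def test_degenerate_geometry_raises():
    # upslope shallower than the "washout": lines meet before the onset
    t = np.arange(0.0, 40.0, 2.0)
    y = np.where(t < 16, 40.0 + 0.5 * t, 10.0 + 3.0 * t)
    with pytest.raises(DegenerateGeometryError, match="degenerate"):
        fit_trilinear(TimeIntensityCurve(t, y), range(4, 9))


def test_washout_cap_excludes_late_samples(protocol):
    """A recirculation-like late drift biases the uncapped washout line;
    capping the washout fit at 70 s restores exact recovery."""
    y = trilinear_values(protocol.times, 40.0, 14.0, 2.0, 20.0, -0.2)
    late = protocol.times > 70.0
    y[late] += 0.4 * (protocol.times[late] - 70.0)
    curve = TimeIntensityCurve(protocol.times, y)
    capped = fit_curve(curve, washout_cap=70.0)
    uncapped = fit_curve(curve)
    assert capped.upslope_slope == pytest.approx(2.0, abs=1e-6)
    assert capped.peak_enhancement == pytest.approx(20.0, abs=1e-6)
    assert abs(uncapped.peak_enhancement - 20.0) > 0.1


# ------------------------------------------------------- fit_curve (composition)

def test_flat_curve_fails_as_non_enhancing(protocol):
    curve = TimeIntensityCurve(protocol.times,
                               np.full(protocol.times.size, 45.0))
    with pytest.raises(StageError) as err:
        fit_curve(curve)
    assert isinstance(err.value.original,
                      (NonEnhancingCurveError, DegenerateGeometryError,
                       InsufficientPhaseSupportError))


def test_composition_equals_manual_three_steps(protocol):
    y = trilinear_values(protocol.times, 40.0, 14.0, 2.0, 20.0, -0.2)
    curve = TimeIntensityCurve(protocol.times, y)
    summary = fit_spline(curve)
    window = select_upslope_window(summary, curve)
    manual = fit_trilinear(curve, window)
    composed = fit_curve(curve)
    assert composed == manual


def test_seeded_sweep_no_crashes_and_invariants_hold(protocol):
    """Across 200 seeded noisy generator curves every successful fit
    satisfies the model invariants; failures are typed errors only."""
    rng = np.random.default_rng(11)
    successes = 0
    for _ in range(200):
        dur = rng.uniform(10.0, 28.0)
        slope = max(rng.normal(2.0, 0.6), 0.5)
        onset = place_onset(dur, protocol, washout_ratio=-0.2 / slope)
        tic, _ = generate_tic(protocol, 40.0, onset, slope, slope * dur,
                              -0.2, noise_sd=3.0, seed=rng)
        try:
            fit = fit_curve(tic)
        except StageError:
            continue
        successes += 1
        assert fit.onset_time < fit.peak_time
        assert fit.peak_enhancement == pytest.approx(
            fit.upslope_slope * (fit.peak_time - fit.onset_time), rel=1e-9)
        w = fit.window_indices
        assert list(w) == list(range(w[0], w[-1] + 1))
    assert successes >= 190


# ----------------------------------------------------------- properties

@pytest.mark.parametrize("shift,scale", [(25.0, 1.0), (-10.0, 1.0),
                                         (0.0, 3.0), (7.5, 0.5)])
def test_shift_scale_equivariance(protocol, shift, scale):
    """Adding c HU shifts only the baseline; scaling by k scales slope,
    peak enhancement and baseline by k."""
    rng = np.random.default_rng(3)
    y = trilinear_values(protocol.times, 40.0, 14.0, 2.0, 24.0, -0.2)
    y = y + rng.normal(0.0, 2.0, y.size)
    ref = fit_curve(TimeIntensityCurve(protocol.times, y))
    mod = fit_curve(TimeIntensityCurve(protocol.times, scale * y + shift))
    assert mod.upslope_slope == pytest.approx(scale * ref.upslope_slope,
                                              rel=1e-9)
    assert mod.peak_enhancement == pytest.approx(
        scale * ref.peak_enhancement, rel=1e-9)
    assert mod.baseline_level == pytest.approx(
        scale * ref.baseline_level + shift, rel=1e-9)


def test_estimated_slope_increases_with_generating_slope(protocol):
    """Holding the noise realisation fixed, a steeper generating upslope
    yields a strictly larger estimated slope."""
    noise = np.random.default_rng(5).normal(0.0, 3.0, protocol.times.size)
    onset = place_onset(12.0, protocol, washout_ratio=-0.1)
    estimates = []
    for slope in (1.5, 2.0, 2.5, 3.0):
        y = trilinear_values(protocol.times, 40.0, onset, slope,
                             slope * 12.0, -0.1 * slope) + noise
        estimates.append(
            fit_curve(TimeIntensityCurve(protocol.times, y)).upslope_slope)
    assert np.all(np.diff(estimates) > 0)


# ------------------------------------------------------ sklearn estimator

def test_estimator_fit_predict_roundtrip(protocol):
    from sklearn.base import clone

    y = trilinear_values(protocol.times, 40.0, 14.0, 2.0, 20.0, -0.2)
    model = TrilinearCurveModel()
    cloned = clone(model)  # params only, no fitted state
    fitted = cloned.fit(protocol.times.reshape(-1, 1), y)
    assert fitted.slope_ == pytest.approx(2.0, abs=1e-6)
    assert fitted.peak_enhancement_ == pytest.approx(20.0, abs=1e-6)
    pred = fitted.predict(protocol.times.reshape(-1, 1))
    assert np.allclose(pred, y, atol=1e-6)
    assert fitted.get_params() == {"smoothing": None, "window_size": 5,
                                   "washout_cap": None}
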