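"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from ctperf import AcquisitionProtocol, TimeIntensityCurve


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def trilinear_values(t, baseline, onset, slope, peak_enhancement,
                     washout_slope):
    """Reference evaluation of the three-phase curve, written directly
    from the geometry (independent of the package's generator)."""
    t = np.asarray(t, dtype=float)
    peak_time = onset + peak_enhancement / slope
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        if ti <= onset:
            out[i] = baseline
        elif ti <= peak_time:
            out[i] = baseline + slope * (ti - onset)
        else:
            out[i] = (baseline + peak_enhancement
                      + washout_slope * (ti - peak_time))
    return out


def _line_rss(t, y):
    if len(t) <= 2:
        return 0.0
    m, b = np.polyfit(t, y, 1)
    return float(((y - (m * t + b)) ** 2).sum())


def exhaustive_partition_rss(t, y, min_phase=2, min_window=2,
                             window_size=None):
    """Brute-force minimum total RSS over all contiguous three-phase
    partitions (constant | line | line).

    ``window_size`` pins the upslope segment length (the pipeline's model
    class); ``None`` searches all window lengths >= ``min_window``.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = len(t)
    best = np.inf
    for i in range(min_phase, n - min_phase - min_window + 1):
        sizes = ([window_size] if window_size
                 else range(min_window, n - min_phase - i + 1))
        for w in sizes:
            j = i + w - 1
            if j > n - 1 - min_phase:
                continue
            rss = (float(((y[:i] - y[:i].mean()) ** 2).sum())
                   + _line_rss(t[i:j + 1], y[i:j + 1])
                   + _line_rss(t[j + 1:], y[j + 1:]))
            best = min(best, rss)
    return best


@pytest.fixture(scope="session")
def oracle_rss():
    return exhaustive_partition_rss


@pytest.fixture()
def uniform_grid_curve():
    """Noiseless trilinear curve on a uniform 2-s grid: baseline 40 HU up
    to t=6, slope 2 HU/s to t=16, washout slope -0.2 after (the 16-sample
    grid keeps two clean phases on each side of the 4-sample upslope)."""
    t = np.arange(0.0, 31.0, 2.0)
    y = trilinear_values(t, 40.0, 6.0, 2.0, 20.0, -0.2)
    return TimeIntensityCurve(t, y, roi_name="tumor")
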