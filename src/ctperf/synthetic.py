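"""Seeded synthetic TICs, 4D phantoms and cohorts.

The generator emulates the structure of the clinical study the biomarker
targets: the interleaved 27-point acquisition grid of the perfusion
protocol, and two vascular-phenotype groups whose feature distributions
(enhancement slope, peak enhancement, pancreas-tumor enhancement
difference, group sizes, median survival) default to the published group
statistics of a 92-patient pancreatic-adenocarcinoma cohort.  Curves are
generated directly in the trilinear family — the biomarker is defined
purely on the TIC, so the generator targets the TIC family rather than a
contrast-kinetics model.

Because the five-sample upslope window of the analysis pipeline can only
represent upslopes spanning five grid samples, the generator places each
patient's enhancement onset so that the open upslope interval contains
exactly five samples of the (non-uniform) grid.  This makes the generating
parameters identifiable by the pipeline; see docs/methods.md for what this
does and does not say about real curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .curve import TimeIntensityCurve
from .errors import CTPerfError
from .phenotype import PerfusionFeatures
from .roi import DEFAULT_LABELS, DynamicSeries, LabelSchema
from .survival import CohortRecord

LN2 = math.log(2.0)


def _default_grid() -> np.ndarray:
    """The 27-point acquisition grid: 13 scans at 2 s intervals from t=0,
    a parenchymal-phase volume at ~35 s, 9 scans at 3 s intervals from
    38 s, the portal-venous scan at 70 s, and late scans at 90/120/150 s."""
    return np.concatenate([
        np.arange(0.0, 25.0, 2.0),       # 13 points, 0..24 s
        [35.0],
        np.arange(38.0, 63.0, 3.0),      # 9 points, 38..62 s
        [70.0, 90.0, 120.0, 150.0],
    ])


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Scan time grid (s) and the bolus arrival offset.

    The perfusion series starts ``arrival_offset`` seconds before the
    measured contrast arrival in the aorta, so tissue enhancement begins
    some seconds after t=0.
    """

    times: np.ndarray = field(default_factory=_default_grid)
    arrival_offset: float = 2.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("protocol times must be strictly increasing")
        object.__setattr__(self, "times", t)

    @classmethod
    def default(cls) -> "AcquisitionProtocol":
        return cls()


@dataclass(frozen=True)
class TrilinearTruth:
    """Generating parameters of one synthetic curve."""

    baseline: float
    onset: float
    slope: float
    peak_enhancement: float
    washout_slope: float

    @property
    def peak_time(self) -> float:
        return self.onset + self.peak_enhancement / self.slope

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        up = self.baseline + self.slope * (t - self.onset)
        wash = (self.baseline + self.peak_enhancement
                + self.washout_slope * (t - self.peak_time))
        return np.where(t <= self.onset, self.baseline,
                        np.where(t <= self.peak_time, up, wash))


@dataclass(frozen=True)
class GroupParams:
    """Feature distribution and size of one vascular-phenotype group.

    Defaults mirror the published group statistics: hypovascular tumors
    enhance more slowly and less than isovascular ones, and the pancreas
    out-enhances hypovascular tumors by ~35 HU but isovascular ones by
    only ~12 HU.
    """

    slope_mean: float
    slope_sd: float
    peak_mean: float
    peak_sd: float
    delta_mean: float
    delta_sd: float
    n: int
    survival_median_days: float

    def __post_init__(self) -> None:
        if min(self.slope_sd, self.peak_sd, self.delta_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if self.n <= 0:
            raise ValueError("group size must be positive")

    @classmethod
    def hypovascular(cls) -> "GroupParams":
        return cls(slope_mean=2.0, slope_sd=0.6, peak_mean=46.8, peak_sd=12.2,
                   delta_mean=35.3, delta_sd=19.4, n=72,
                   survival_median_days=320.0)

    @classmethod
    def isovascular(cls) -> "GroupParams":
        return cls(slope_mean=2.9, slope_sd=1.1, peak_mean=69.9, peak_sd=22.1,
                   delta_mean=12.0, delta_sd=9.1, n=20,
                   survival_median_days=377.0)


# physical truncation bounds for feature draws
MIN_SLOPE = 0.1      # HU/s
MIN_PEAK = 5.0       # HU
# upslope durations representable by a five-sample window on the grid
MIN_DURATION = 8.5   # s
MAX_DURATION = 60.0  # s


_BIG_COST = 100.0

_deriv_op_cache: dict[tuple, np.ndarray] = {}


def _derivative_operator(times_key: tuple) -> np.ndarray:
    """Matrix D with (D @ y)_j = spline-derivative of y at sample j.

    For a fixed grid and penalty the smoothing spline is linear in the
    values, so derivative evaluation at the sample times is a single
    matrix; building it once (one spline fit per unit vector) makes the
    placement search cheap.
    """
    if times_key not in _deriv_op_cache:
        from scipy.interpolate import make_smoothing_spline

        from .trilinear import default_smoothing

        t = np.asarray(times_key, dtype=float)
        lam = default_smoothing(t)
        n = t.size
        D = np.empty((n, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            D[:, i] = make_smoothing_spline(t, e, lam=lam).derivative()(t)
        _deriv_op_cache[times_key] = D
    return _deriv_op_cache[times_key]


def _noiseless_argmax(times: np.ndarray, onset: float, duration: float,
                      washout_ratio: float) -> int:
    """Derivative-argmax index of the default smoothing spline for the
    noiseless unit-slope proxy curve."""
    truth = TrilinearTruth(baseline=0.0, onset=onset, slope=1.0,
                           peak_enhancement=duration,
                           washout_slope=washout_ratio)
    D = _derivative_operator(tuple(times.tolist()))
    return int(np.argmax(D @ truth.evaluate(times)))


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = t.size
    st = t.sum()
    sy = y.sum()
    den = n * (t * t).sum() - st * st
    m = (n * (t * y).sum() - st * sy) / den
    return m, (sy - m * st) / n


def _three_phase_errors(t: np.ndarray, y: np.ndarray, w0: int, w1: int,
                        duration: float) -> float:
    """Relative slope + peak error of the three-phase OLS fit with the
    upslope window [w0, w1] on the unit-slope proxy curve."""
    base = float(np.mean(y[:w0]))
    m, b = _ols(t[w0:w1 + 1], y[w0:w1 + 1])
    mw, bw = _ols(t[w1 + 1:], y[w1 + 1:])
    if m <= 0 or m <= mw:
        return _BIG_COST
    peak_t = (bw - b) / (m - mw)
    onset_t = (base - b) / m
    if onset_t >= peak_t:
        return _BIG_COST
    peak_est = m * peak_t + b - base
    return abs(m - 1.0) + abs(peak_est - duration) / duration


def _placement_cost(times: np.ndarray, onset: float, duration: float,
                    window_size: int, washout_ratio: float) -> tuple:
    """Noiseless estimation error of the full pipeline for a unit-slope
    curve with this onset, plus a robustness term for +-1 window jitter.

    The smoothing spline is linear in the values, so the derivative argmax
    — and hence the selected window — is identical for the unit-slope
    proxy and any actual curve with the same onset and duration; the
    noiseless relative errors evaluated here are therefore exact.
    """
    from .trilinear import select_upslope_window, SplineSummary

    truth = TrilinearTruth(baseline=0.0, onset=onset, slope=1.0,
                           peak_enhancement=duration,
                           washout_slope=washout_ratio)
    y = truth.evaluate(times)
    curve = TimeIntensityCurve(times, y)
    D = _derivative_operator(tuple(times.tolist()))
    deriv = D @ y
    summary = SplineSummary(smoothed_values=y, derivative=deriv,
                            argmax_derivative_index=int(np.argmax(deriv)),
                            smoothing=np.nan)
    try:
        window = select_upslope_window(summary, curve, window_size)
    except Exception:
        return (2, np.inf)
    n = times.size
    costs = []
    for shift in (-1, 0, 1):
        s0, s1 = window.start + shift, window[-1] + shift
        if s0 < 2 or s1 > n - 3:
            costs.append(_BIG_COST)
            continue
        costs.append(_three_phase_errors(times, y, s0, s1, duration))
    # exact noiseless recovery takes priority, but only when a one-sample
    # window shift is not catastrophic (a fragile exact placement loses to
    # a robust near-exact one under measurement noise)
    combined = costs[1] + 0.25 * (costs[0] + costs[2])
    exact = 0 if (costs[1] < 1e-9 and combined < 1.0) else 1
    return (exact, combined)


def _place_onset_impl(times_key: tuple, duration: float,
                      window_size: int, washout_ratio: float) -> float:
    times = np.asarray(times_key, dtype=float)
    n = times.size
    half = (window_size - 1) // 2
    lo, hi = times[1], times[-2] - duration
    if hi <= lo:
        raise CTPerfError(
            f"no feasible onset: upslope duration {duration:.1f} s cannot "
            f"be placed on this grid"
        )
    candidates: list[float] = []
    for c in range(2 + half, n - 2 - half):
        mid = times[c] - duration / 2.0
        cands = [mid]
        # the smoothed-derivative maximum can skew off the upslope midpoint
        # (asymmetric neighbourhoods, washout steepness); chase the fixed
        # point where the selected window is centred where intended
        onset = mid
        for _ in range(3):
            a = _noiseless_argmax(times, onset, duration, washout_ratio)
            if a is None or a == c:
                break
            onset = onset + (times[c] - times[a])
            if lo <= onset <= hi:
                cands.append(onset)
        # onset or peak snapped onto a sample is robust to window jitter:
        # the shared sample lies on both lines of the kink it marks
        for base_onset in list(cands):
            j = int(np.searchsorted(times, base_onset, side="right")) - 1
            if 0 <= j < n:
                cands.append(times[j])
            k = int(np.searchsorted(times, base_onset + duration,
                                    side="left"))
            if 0 <= k < n:
                cands.append(times[k] - duration)
        candidates.extend(x for x in cands if lo <= x <= hi)
    # onset on any sample, and peak on any sample, are also candidates
    candidates.extend(x for x in times if lo <= x <= hi)
    candidates.extend(x - duration for x in times
                      if lo <= x - duration <= hi)
    candidates = sorted({round(x, 9) for x in candidates})
    best_cost, best_onset = (2, np.inf), None
    for onset in candidates:
        cost = _placement_cost(times, onset, duration, window_size,
                               washout_ratio)
        if cost < best_cost:
            best_cost, best_onset = cost, onset
    if best_onset is None or not np.isfinite(best_cost[1]):
        raise CTPerfError(
            f"no feasible onset: upslope duration {duration:.1f} s cannot "
            f"be placed on this grid"
        )
    return float(best_onset)


_placement_cache: dict[tuple, float] = {}


def place_onset(duration: float, protocol: AcquisitionProtocol,
                window_size: int = 5,
                washout_ratio: float = -0.1) -> float:
    """Place the enhancement onset so the upslope is identifiable by the
    fixed five-sample analysis window on this (non-uniform) grid.

    Candidate onsets (upslope midpoint on a sample, or onset/peak snapped
    onto a sample) are scored by the noiseless estimation error of the
    full localisation-plus-fit pipeline, including a penalty for the
    error under a one-sample window shift; the placement with the
    smallest score wins.  For durations spanning five samples the error
    is exactly zero; longer upslopes get the placement that leaks the
    fewest, least-harmful samples into the neighbouring phases.

    ``washout_ratio`` is the washout-to-upslope slope ratio of the curve
    being placed (the proxy curve must share it for the spline argmax to
    transfer exactly).  Results are cached per exact argument tuple.
    """
    key = (tuple(protocol.times.tolist()), float(duration), window_size,
           float(washout_ratio))
    if key not in _placement_cache:
        _placement_cache[key] = _place_onset_impl(key[0], key[1],
                                                  window_size, key[3])
    return _placement_cache[key]


def generate_tic(protocol: AcquisitionProtocol, baseline: float, onset: float,
                 slope: float, peak_enhancement: float,
                 washout_slope: float = -0.2, noise_sd: float = 0.0,
                 seed: int | np.random.Generator | None = None,
                 roi_name: str = "roi"
                 ) -> tuple[TimeIntensityCurve, TrilinearTruth]:
    """Sample an exact trilinear curve on the grid plus i.i.d. Gaussian
    noise; the generating parameters are returned alongside."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if peak_enhancement <= 0:
        raise ValueError("peak_enhancement must be positive")
    truth = TrilinearTruth(baseline=baseline, onset=onset, slope=slope,
                           peak_enhancement=peak_enhancement,
                           washout_slope=washout_slope)
    t = protocol.times
    if not (t[0] <= onset and truth.peak_time <= t[-1]):
        raise CTPerfError(
            f"onset {onset:.1f} s or peak {truth.peak_time:.1f} s falls "
            f"outside the grid [{t[0]:.0f}, {t[-1]:.0f}] s"
        )
    values = truth.evaluate(t)
    if noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        values = values + rng.normal(0.0, noise_sd, size=t.size)
    return TimeIntensityCurve(t, values, roi_name=roi_name), truth


@dataclass
class SyntheticPatient:
    """One simulated patient: ground truth, curves and outcome."""

    patient_id: str
    is_isovascular: int
    true_features: PerfusionFeatures
    tumor_tic: TimeIntensityCurve | None
    pancreas_tic: TimeIntensityCurve | None
    tumor_truth: TrilinearTruth | None
    pancreas_truth: TrilinearTruth | None
    survival_days: float
    event: int

    def to_record(self, features: PerfusionFeatures | None = None
                  ) -> CohortRecord:
        """CohortRecord with fitted features (default: the ground truth)."""
        return CohortRecord(
            patient_id=self.patient_id,
            features=features if features is not None else self.true_features,
            phenotype_visual=self.is_isovascular,
            survival_days=self.survival_days,
            event=self.event,
        )


def generate_cohort(hypo: GroupParams | None = None,
                    iso: GroupParams | None = None,
                    noise_sd: float = 3.0,
                    seed: int | None = 0,
                    protocol: AcquisitionProtocol | None = None,
                    baseline_mean: float = 40.0,
                    baseline_sd: float = 5.0,
                    pancreas_slope_mean: float = 3.5,
                    pancreas_slope_sd: float = 0.5,
                    feature_corr: float = 0.6,
                    washout_slope: float = -0.2,
                    censor_horizon_days: float = 1095.0,
                    max_tries: int = 200,
                    curves: bool = True) -> list[SyntheticPatient]:
    """Generate a full two-group cohort with paired tumor/pancreas curves
    and censored survival times.

    Per patient the true (slope, peak, delta) triple is drawn from the
    group's truncated-normal distributions, the pancreas peak is tumor
    peak + delta, both curves are synthesised on the grid with Gaussian
    noise, and an exponential survival time with the group median is
    administratively censored at ``censor_horizon_days``.  Draws whose
    implied upslope duration has no five-sample window on the grid are
    redrawn (bounded retries).

    ``feature_corr`` is the Gaussian-copula correlation between slope and
    peak enhancement (and between pancreas slope and pancreas peak): both
    scale with regional perfusion, so independent draws would produce
    unphysiological tumors with very high peaks but near-zero slopes.
    Marginal distributions are unaffected.

    With ``curves=False`` only features and outcomes are drawn (no TIC
    synthesis); at ``noise_sd=0`` the random stream is identical either
    way, since noiseless curve synthesis consumes no random numbers.
    """
    hypo = hypo or GroupParams.hypovascular()
    iso = iso or GroupParams.isovascular()
    protocol = protocol or AcquisitionProtocol.default()
    rng = np.random.default_rng(seed)
    patients: list[SyntheticPatient] = []

    rho = feature_corr
    rho_c = math.sqrt(max(1.0 - rho ** 2, 0.0))

    def _retry(draw, ok, what, tries=None):
        for _ in range(tries or max_tries):
            x = draw()
            if ok(x):
                return x
        raise CTPerfError(
            f"no feasible draw for {what} after {tries or max_tries} tries"
        )

    # peak and delta are drawn unconditionally (their marginals stay
    # exact); the slopes absorb the duration-feasibility truncation
    for group, params, label in (("hypo", hypo, 0), ("iso", iso, 1)):
        panc_peak_sd = math.hypot(params.peak_sd, params.delta_sd)
        for k in range(params.n):
            who = f"{group} patient {k}"
            zp = _retry(
                rng.standard_normal,
                lambda z: params.peak_mean + params.peak_sd * z > MIN_PEAK,
                f"{who} peak")
            peak = params.peak_mean + params.peak_sd * zp
            slope = _retry(
                lambda: params.slope_mean + params.slope_sd
                * (rho * zp + rho_c * rng.standard_normal()),
                lambda s: s > MIN_SLOPE
                and MIN_DURATION < peak / s < MAX_DURATION,
                f"{who} slope")
            # delta is redrawn only in the rare case that the implied
            # pancreas peak leaves no feasible pancreas slope
            for _ in range(max_tries):
                delta = (rng.normal(params.delta_mean, params.delta_sd)
                         if params.delta_sd > 0 else params.delta_mean)
                panc_peak = peak + delta
                if panc_peak <= MIN_PEAK:
                    continue
                zpp = ((panc_peak - params.peak_mean - params.delta_mean)
                       / panc_peak_sd) if panc_peak_sd > 0 else 0.0
                try:
                    panc_slope = _retry(
                        lambda: pancreas_slope_mean + pancreas_slope_sd
                        * (rho * zpp + rho_c * rng.standard_normal()),
                        lambda s: s > MIN_SLOPE
                        and MIN_DURATION < panc_peak / s < MAX_DURATION,
                        f"{who} pancreas slope", tries=50)
                except CTPerfError:
                    continue
                break
            else:
                raise CTPerfError(
                    f"no feasible delta/pancreas draw for {who} after "
                    f"{max_tries} tries"
                )
            dur_t = peak / slope
            dur_p = panc_peak / panc_slope
            baseline = rng.normal(baseline_mean, baseline_sd) \
                if baseline_sd > 0 else baseline_mean
            if curves:
                onset_t = place_onset(dur_t, protocol,
                                      washout_ratio=washout_slope / slope)
                onset_p = place_onset(dur_p, protocol,
                                      washout_ratio=washout_slope / panc_slope)
                tumor_tic, tumor_truth = generate_tic(
                    protocol, baseline, onset_t, slope, peak,
                    washout_slope=washout_slope, noise_sd=noise_sd, seed=rng,
                    roi_name="tumor")
                panc_tic, panc_truth = generate_tic(
                    protocol, baseline, onset_p, panc_slope, panc_peak,
                    washout_slope=washout_slope, noise_sd=noise_sd, seed=rng,
                    roi_name="pancreas")
            else:
                tumor_tic = panc_tic = tumor_truth = panc_truth = None
            raw_surv = rng.exponential(params.survival_median_days / LN2)
            event = int(raw_surv <= censor_horizon_days)
            patients.append(SyntheticPatient(
                patient_id=f"{group}_{k + 1:03d}",
                is_isovascular=label,
                true_features=PerfusionFeatures(slope, peak, delta),
                tumor_tic=tumor_tic,
                pancreas_tic=panc_tic,
                tumor_truth=tumor_truth,
                pancreas_truth=panc_truth,
                survival_days=float(min(raw_surv, censor_horizon_days)),
                event=event,
            ))
    return patients


# ---------------------------------------------------------------------------
# 4D digital phantom

#: Compartment curve parameters of the default phantom: parenchyma and a
#: hypovascular lesion enhance on tissue scales; the vessel carries an
#: arterial first-pass bolus.
DEFAULT_PHANTOM_COMPARTMENTS: dict[str, TrilinearTruth] = {
    "pancreas": TrilinearTruth(40.0, 16.0, 3.0, 80.0, -0.25),
    "tumor": TrilinearTruth(40.0, 20.5, 2.0, 46.0, -0.2),
    "vessel": TrilinearTruth(40.0, 4.0, 30.0, 260.0, -1.5),
    "background": TrilinearTruth(20.0, 20.0, 0.01, 0.5, 0.0),
}


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def generate_phantom(protocol: AcquisitionProtocol | None = None,
                     shape: tuple[int, int, int] = (48, 48, 48),
                     schema: LabelSchema | None = None,
                     tumor_radius: float = 6.0,
                     vessel_radius: float = 2.0,
                     compartments: dict[str, TrilinearTruth] | None = None,
                     noise_sd: float = 0.0,
                     jitter_voxels: int = 0,
                     seed: int | None = 0
                     ) -> tuple[DynamicSeries, np.ndarray,
                                dict[str, TimeIntensityCurve]]:
    """Build a 4D phantom: an ellipsoidal pancreas with an embedded tumor
    and a vessel running through it, each compartment following its
    ground-truth TIC plus optional voxel noise and per-timepoint rigid
    jitter (integer-voxel shifts emulating residual motion).

    Returns the dynamic series, the (unjittered) label map, and the
    noiseless compartment ground-truth curves.
    """
    protocol = protocol or AcquisitionProtocol.default()
    schema = schema or LabelSchema()
    compartments = compartments or DEFAULT_PHANTOM_COMPARTMENTS
    if any(s < 32 for s in shape):
        raise ValueError(f"phantom shape must be >= 32 per axis, got {shape}")
    center = tuple(s / 2.0 for s in shape)
    panc_radii = tuple(0.36 * s for s in shape)
    if tumor_radius >= min(panc_radii):
        raise ValueError(
            f"lesion radius {tumor_radius} does not fit inside the pancreas "
            f"(semi-axes {tuple(round(r, 1) for r in panc_radii)})"
        )

    labels = np.full(shape, DEFAULT_LABELS["background"], dtype=np.int32)
    labels[_ellipsoid_mask(shape, center, panc_radii)] = schema["pancreas"]
    tumor_center = (center[0], center[1] + 0.3 * panc_radii[1], center[2])
    labels[_ellipsoid_mask(shape, tumor_center, (tumor_radius,) * 3)] = \
        schema["tumor"]
    # vessel: a cylinder along z through the tumor centre
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    vessel = ((yy - tumor_center[1]) ** 2 + (xx - tumor_center[2]) ** 2
              <= vessel_radius ** 2)
    vessel = vessel & (np.abs(zz - center[0]) <= panc_radii[0])
    labels[vessel] = schema["abdominal_aorta"]

    t = protocol.times
    curves = {}
    name_by_code = {
        DEFAULT_LABELS["background"]: "background",
        schema["pancreas"]: "pancreas",
        schema["tumor"]: "tumor",
        schema["abdominal_aorta"]: "vessel",
    }
    for code, name in name_by_code.items():
        curves[name] = compartments[name].evaluate(t)

    rng = np.random.default_rng(seed)
    volumes = np.empty((t.size,) + shape, dtype=float)
    for ti in range(t.size):
        vol = np.empty(shape, dtype=float)
        for code, name in name_by_code.items():
            vol[labels == code] = curves[name][ti]
        if noise_sd > 0:
            vol = vol + rng.normal(0.0, noise_sd, size=shape)
        if jitter_voxels > 0:
            shift = rng.integers(-jitter_voxels, jitter_voxels + 1, size=3)
            vol = np.roll(vol, tuple(shift), axis=(0, 1, 2))
        volumes[ti] = vol

    series = DynamicSeries(volumes, t)
    truths = {name: TimeIntensityCurve(t, curves[name], roi_name=name)
              for name in ("pancreas", "tumor", "vessel")}
    return series, labels, truths


def cohort_to_tic_csvs(patients, out_dir, noise_suffix: bool = False) -> None:
    """Write each patient's tumor and pancreas TICs as standard CSVs
    (``<patient_id>_tumor.csv`` / ``<patient_id>_pancreas.csv``)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in patients:
        p.tumor_tic.to_csv(out / f"{p.patient_id}_tumor.csv")
        p.pancreas_tic.to_csv(out / f"{p.patient_id}_pancreas.csv")
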