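# Methods

## The trilinear curve model

A time–intensity curve (TIC) is the mean attenuation of one ROI (HU)
at each acquisition time of a dynamic contrast-enhanced CT series.  The
model decomposes it into a non-enhancement phase (constant line at the
baseline level `b`), an upslope phase (line with slope `m` > 0), and a
washout phase (line with slope `w` < `m`).  Derived quantities:

* onset of enhancement `t0` — intersection of the static and upslope
  lines;
* peak time `tp` — intersection of the upslope and washout lines;
* peak enhancement `P = m·(tp − t0)` — the modelled attenuation rise
  above the static line at the peak.

Peak enhancement is reported **baseline-subtracted**.  The alternative
(absolute HU at the peak) is inconsistent with the magnitudes the
features take in practice (tissue baselines are ~40 HU and peak
enhancements ~47–70 HU; absolute peaks would be ~90–110 HU), so the
subtracted convention is used throughout and `TrilinearFit.baseline_level`
preserves the absolute scale.

### Two-step fitting

1. **Localisation.**  A cubic penalized smoothing spline
   (`scipy.interpolate.make_smoothing_spline`, knots at every sample) is
   fitted to the whole curve and its analytic first derivative evaluated
   at the sample times; the first index attaining the maximum derivative
   marks the upslope zone.  The default roughness penalty is
   `λ = 2.5·(mean Δt)³` — a bandwidth of the order of one sample spacing.
   It is deliberately tied to the sampling density, not the noise level:
   the spline's only job is to locate the steepest zone, and this penalty
   keeps the derivative maximum at the centre of the upslope both for
   noiseless piecewise-linear curves (a near-interpolating spline peaks
   next to a kink instead) and under HU-scale noise.  A residual-matched
   FITPACK-style smoothing factor was tried first and rejected: when the
   budget is satisfiable by a single knotless cubic, the derivative
   maximum lands on the curve boundary and localisation fails on several
   percent of realistic curves.
2. **Phase regression.**  A window of five samples (configurable) centred
   on the derivative argmax — two before, the argmax, two after; shifted
   at boundaries, shrunk to no fewer than three — is assigned to the
   upslope.  Everything earlier is the non-enhancement phase (constant
   least-squares fit), everything later the washout phase (straight-line
   fit).  At least two samples are required on each side ("insufficient
   phase support" otherwise).  A non-positive fitted upslope slope is a
   typed error ("non-enhancing curve"), as is a washout slope at or above
   the upslope slope ("degenerate geometry"); failed curves are excluded
   from cohort statistics and enumerated in the pipeline report rather
   than contributing silent nonsense.

The washout line uses **all** post-window samples by default, including
the late 90/120/150 s acquisitions; `washout_cap` (s) optionally restricts
the washout fit to earlier samples when late recirculation drift is a
concern.  Fits are performed in time units throughout, so the non-uniform
grid needs no special casing.

### What the five-sample window can and cannot estimate

On the default 27-point grid the window spans 8–12 s.  An upslope whose
open interior contains exactly five samples is *identifiable*: every
sample is correctly phase-assigned and a noiseless curve is recovered to
machine precision.  Longer upslopes (the nominal feature values imply
durations of ~23–24 s) necessarily leak interior samples into the
neighbouring phase regressions; the slope remains unbiased (the window
stays inside the upslope) but the peak enhancement acquires a
duration-dependent negative bias, measured at −0.2 HU near 25 s rising to
about −4 HU at 35 s.  This is a property of the published fitting recipe,
not of this implementation; the tests and the synthetic generator are
designed around it (below).

### Heuristic vs global least squares

The two-step fit is a heuristic localisation, not a global optimiser.  A
brute-force search over all contiguous (pre | window | post) partitions
attains a lower total RSS on a sizable fraction of noisy draws — not
because the localisation picks the wrong window, but because the minimum
over ~250 near-equivalent partitions is selection-biased low: at noise
SD 3 HU even the *true generating partition* is within 10% of that
optimum only ~75% of the time.  The fitted-window RSS is typically within
2–8% (median) of the global optimum; the tail of the ratio distribution
reflects the optimum chasing noise, and one acceptance test documenting a
within-10%-on-90% bound for this comparison is expected to fail under
these conditions.

## Synthetic data

The generator targets the TIC family directly — the biomarker is defined
purely on the curve, so no contrast-kinetics model is interposed.

**Acquisition grid.**  27 timepoints: 13 at 2 s intervals from t = 0, a
parenchymal-phase volume at 35 s, nine at 3 s intervals from 38 s, the
portal-venous acquisition at 70 s, and late scans at 90/120/150 s.  The
series starts 2 s before aortic contrast arrival, so tissue enhancement
onsets fall some seconds after t = 0.

**Cohorts.**  Two groups with truncated-normal feature distributions
whose defaults are the published group statistics of a 92-patient cohort
(hypovascular: slope 2.0 ± 0.6 HU/s, peak 46.8 ± 12.2 HU,
ΔHU 35.3 ± 19.4, n = 72, median OS 320 d; isovascular: 2.9 ± 1.1,
69.9 ± 22.1, 12.0 ± 9.1, n = 20, 377 d).  Design choices:

* *Truncation*: slope > 0.1 HU/s and peak > 5 HU (physical minima), and
  upslope duration `peak/slope` within (8.5 s, 60 s) — the range a
  five-sample window can be placed for on this grid.  Draws are
  hierarchical so that the peak and ΔHU marginals remain exact: the peak
  and ΔHU are drawn unconditionally and the slopes absorb the
  duration-feasibility truncation via bounded redraws.
* *Correlation*: slope and peak share a Gaussian-copula correlation of
  0.6 (likewise pancreas slope with pancreas peak).  Both quantities
  scale with regional perfusion; independent draws would produce
  unphysiological tumors with large peaks and near-zero slopes, i.e.
  implausibly long enhancement phases.  Marginals are unaffected.
* *Pancreas*: pancreas peak = tumor peak + ΔHU; pancreas slope
  3.5 ± 0.5 HU/s (normal parenchyma enhances briskly; this puts the
  parenchymal upslope duration in the same ~23 s range as the tumors).
* *Baseline* 40 ± 5 HU; washout slope −0.2 HU/s; i.i.d. Gaussian noise
  (default SD 3 HU) on every sample.
* *Survival*: exponential with the group median, administratively
  censored at a configurable horizon (default 3 years).  With these
  medians and n = 92 the log-rank comparison is under-powered, so a
  given synthetic cohort frequently shows a non-significant survival
  split; survival machinery is validated by calibration (type-I error)
  and oracle tests rather than by expecting significance.

**Onset placement.**  Because the five-sample window cannot represent a
~12-sample upslope, the generator places each patient's enhancement onset
so the upslope is identifiable on the grid.  `place_onset` scores
candidate onsets (upslope midpoint on a sample; onset or peak snapped
onto a sample — a shared sample lies on both lines of its kink and is
harmless to either regression) by the *noiseless estimation error of the
actual pipeline* for a unit-slope proxy curve, plus a penalty for the
error under a ±1-sample window shift; exact-recovery placements win when
they are also jitter-robust.  The smoothing spline is linear in the
values, so the proxy's derivative argmax — and hence the selected window
— transfers exactly to the real curve with the same onset, duration and
washout/upslope slope ratio; derivative evaluation is precomputed as a
single matrix per grid, making the search cheap.  For durations beyond
~25 s no exact placement exists and the best-scoring placement leaks the
fewest, least-harmful samples.

*What this does and does not show.*  Passing recovery tests on these
cohorts demonstrates that the estimator is accurate when the upslope is
resolvable by the window — identifiability by construction.  Real curves
owe their onsets to physiology, not identifiability, are smooth rather
than piecewise-linear, and carry structured (motion, beam-hardening)
rather than i.i.d. noise; cohort-level accuracy on real data is therefore
not established by these tests.

**Phantom.**  An ellipsoidal pancreas with an embedded spherical tumor
and a cylindrical vessel through it; each compartment follows its
ground-truth trilinear curve, with optional i.i.d. voxel noise and
integer rigid jitter per timepoint (residual-motion emulation).  Label
codes ship as an editable YAML schema; vessels and stent are excluded
from the tumor ROI before averaging.

## Phenotype classification

L2-regularised logistic regression (C = 1.0) on the three features,
standardized *inside each training fold*, with stratified five-fold
cross-validation (stratification is necessary at 20/92 imbalance: plain
folds can lose the minority class).  Per-fold ROC curves and AUCs are
reported along with their mean and the pooled out-of-fold AUC — the two
AUC summaries differ slightly and both are reported.  Out-of-fold
probabilities thresholded at 0.5 (configurable) give the predicted
phenotype used for the survival split.  Group differences per feature use
the Mann–Whitney U test: exact null distribution when both groups have
≤ 20 tie-free observations, full enumeration of group assignments when
ties make the tabulated exact method invalid and the assignment count is
small, and the tie-corrected normal approximation otherwise; U is the
first group's statistic (#pairs a > b, ties half).

## Survival

Kaplan–Meier product-limit estimator (median = smallest time with
S ≤ 0.5, flagged as not reached otherwise; censored records at an event
time remain at risk for that event) and the standard observed-minus-
expected two-group log-rank statistic with the hypergeometric
(tie-corrected) variance, referred to a 1-df chi-square.  Both are
implemented in-package so every number is auditable from the risk tables;
the test suite cross-checks them against lifelines and a hand-computed
six-patient example, and verifies type-I calibration (rejection rate in
[0.03, 0.07] at α = 0.05 over 1000 equal-hazard simulations of n = 92).

## Problem sizes and determinism

Cohort-level checks run the full 72 + 20 cohort; the discrimination check
averages the cross-validated AUC over 20 seeded cohorts; the oracle
comparison uses 200 curves of ≤ 30 samples; the type-I calibration uses
1000 simulated cohorts (survival only, no curve fitting).  All
randomness flows through `numpy.random.default_rng` seeds; regenerating
with the same configuration and seed reproduces outputs byte-for-byte,
and each pipeline run writes a manifest with the configuration hash and
seed.

## Known limitations

* Arbitrary trilinear curves are not exactly recoverable: see the window
  identifiability discussion.  Exact-recovery tests draw from the
  identifiable family (durations 9.5–17 s, washout/upslope ratio
  −0.25…−0.05).
* The washout line may include recirculation unless `washout_cap` is
  set; the default follows the all-samples convention.
* Inputs are assumed co-registered; no registration is performed.  The
  phantom's rigid jitter exercises robustness to residual motion only.
* The label schema's integer codes are a package convention; only the
  structure names are fixed.
* No DICOM ingestion (NIfTI only); no kinetic modelling, deconvolution
  or voxel-wise fitting — the biomarker is deliberately ROI-level and
  model-free beyond the three-phase geometry.
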