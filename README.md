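# ctperf

Semi-automated CT-perfusion (CTP) biomarker analysis for pancreatic
tumors: trilinear time–intensity-curve fitting, vascular phenotyping, and
survival comparison.

About 10–20% of pancreatic ductal adenocarcinomas are *isoattenuating* on
contrast-enhanced CT — visually indistinguishable from the surrounding
parenchyma — and tumor vascularity carries prognostic information.  This
package implements a quantitative CTP biomarker for that problem: it turns
a dynamic CT series plus an anatomical label map into per-region
time–intensity curves (TICs), fits a robust non-parametric curve model to
each, derives three perfusion features per patient, classifies tumors into
iso- vs hypovascular phenotypes with a cross-validated logistic model, and
compares overall survival between phenotypes.  A seeded synthetic
generator (curves, cohorts and 4D phantoms) makes every stage testable
without patient data.

## The model

For one ROI, the TIC is mean attenuation (HU) against acquisition time
(s).  The **trilinear model** separates it into three phases:

```
            non-enhancement     upslope          washout
value(t) =  b                   b + m·(t − t0)   b + P + w·(t − tp)
```

* the **static line** `b` (baseline attenuation),
* the **upslope line** with slope `m` (enhancement slope, HU/s),
* the **washout line** with slope `w`.

Fitting is two-step: a cubic smoothing spline locates the steepest point
of the curve, a five-sample window centred there is assigned to the
upslope phase, and each phase gets an ordinary least-squares line.  The
intersection of the static and upslope lines is the **start of
enhancement** `t0`; the intersection of the upslope and washout lines is
the peak, and the **peak enhancement** `P` (HU) is its height above the
static line.  The window covers only the first part of the rise so that
recirculation does not contaminate the slope.

Three features feed the phenotype classifier: tumor slope `m_t` (HU/s),
tumor peak enhancement `P_t` (HU), and the enhancement difference
`ΔHU = P_pancreas − P_tumor` (positive for hypovascular tumors).  A
logistic regression on standardized features, evaluated with stratified
five-fold cross-validation (per-fold ROC/AUC), predicts the visual
phenotype; Kaplan–Meier curves and a log-rank test compare survival
between phenotype groups.

## Worked example

Run the full pipeline on the default synthetic cohort (72 hypovascular +
20 isovascular patients on the 27-point acquisition grid, noise SD 3 HU):

```python
from ctperf.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(output_dir="demo_out",
                     synthetic={"seed": 42, "noise_sd": 3.0},
                     classify={"seed": 42})
res = run_pipeline(cfg)
print(res.phenotype_report["mean_auc"])
```

This prints, per feature, the fitted group statistics and Mann–Whitney
p-values, and the cross-validated discrimination:

```
n_fitted: 92  n_failed: 0
mean fold AUC: 0.903   pooled AUC: 0.883
tumor_slope  hypo   1.98 +/-  0.56   iso   2.88 +/-  0.96   p = 2.27e-05
tumor_peak   hypo  44.36 +/- 12.26   iso  63.31 +/- 24.72   p = 8.19e-04
delta_peak   hypo  37.79 +/- 21.58   iso  13.51 +/- 10.64   p = 4.94e-06
```

Reading: the isovascular group enhances faster (2.88 vs 1.98 HU/s) and
higher (63 vs 44 HU) than the hypovascular group, its enhancement
difference to normal parenchyma is small (13.5 vs 37.8 HU), all three
contrasts are highly significant, and the classifier reproduces the
visual phenotype with a mean per-fold AUC of 0.90.  Artifacts
(`features.csv`, ROC points, KM curves, fit diagnostics, a manifest with
the config hash and seed) land in `demo_out/`.

The same pipeline is available from the shell:

```bash
ctp synth cohort --seed 42 --out-dir cohort/     # TIC CSVs + cohort table
ctp fit cohort/hypo_001_tumor.csv                # one trilinear fit, JSON
ctp synth phantom --seed 1 --out-dir phantom/    # 4D NIfTI phantom
ctp extract phantom/series.nii.gz phantom/labels.nii.gz \
    --times phantom/times.json --roi tumor --out tumor_tic.csv
```

`ctp extract` overlays the label map on every timepoint and averages the
ROI, removing vessel and stent voxels from the tumor ROI before averaging.

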