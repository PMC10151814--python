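# cmrqc

Contour-based, multilevel quality control of cardiac short-axis cine
segmentations.

## What this is for

Automated (CNN-based) segmentation of short-axis cardiovascular magnetic
resonance (CMR) stacks is routinely judged by overall Dice scores and mean
differences in clinical parameters — numbers that can hide exactly the
errors that matter clinically: slices segmented when they should not be (or
vice versa) near the base and apex, displaced or fragmented contours, and
large per-slice volume errors in basal slices. `cmrqc` implements the full
evaluation pipeline needed to expose those errors when comparing a reader
(typically a neural network) against an expert annotation:

* **Clinical parameters** by Simpson disc summation from subpixel polygon
  contours: LVEDV, LVESV, LVEF, RVEDV, RVESV, RVEF, and LV myocardial mass
  (at ED, density 1.05 g/ml).
* **Contour-level geometric metrics** computed on polygons (not rasterised
  masks): Dice = 2|A∩B|/(|A|+|B|) by polygon clipping, and the Hausdorff
  distance Hd(A,B) = max(sup_{a∈A} inf_{b∈B} d(a,b), sup_{b∈B} inf_{a∈A} d(a,b))
  on densely resampled boundaries, both in physical mm.
* **Segmentation-decision metrics** per slice: precision = tp/(tp+fp),
  recall = tp/(tp+fn), where tp counts slices segmented by both readers.
* **Slice-position stratification**: the expert's most basal segmented
  slice plus any reader false positives above it form the basal block, the
  symmetric rule defines the apical block, and everything between is
  midventricular — so errors can be attributed to the anatomically hard
  regions.
* **Two Dice averaging conventions**: over all slices (a slice segmented by
  neither reader scores 100%, by only one reader 0%; mean only) and over
  slices segmented by both (mean ± sd).
* **Statistics**: paired two-sided t-tests on per-case parameter
  differences, Pearson correlations pooled across parameters via Fisher's
  z′ (tanh of the mean atanh), ICC(3,1) (two-way mixed-effects, consistency,
  single rater) with F-based 95% CIs, Bland-Altman limits of agreement, and
  CI-within-tolerance equivalence testing.
* **Synthetic phantoms**: since clinical contour datasets are rarely
  shareable, a generator produces paired expert/AI-like contour stacks with
  analytic ground truth and parametric error models (radial bias,
  translation, basal/apical decision errors, fragmentation, smooth boundary
  jitter), so every stage of the pipeline can be validated against closed
  forms.

The intended users are scientists evaluating segmentation models for
cardiac function quantification and developers of segmentation QC tooling.

## Worked example

```python
from cmrqc import (ErrorModel, make_cohort, compare_readers)

# 29 synthetic cases; the "AI" reader under-segments the LV cavity by 0.5 mm
# radially and sometimes drops the basal slice
models = [
    ErrorModel("radial_bias", {"delta_mm": -0.5}, structures=("lv_endo",)),
    ErrorModel("basal_decision", {"p_drop_anchor": 0.3}),
]
cohort = make_cohort(29, models=models, seed=7)
result = compare_readers(cohort.expert_stacks, {"ai": cohort.reader_stacks})

print(result.param_comparisons["ai"].loc["lvedv_ml"])
print(result.stratified["ai"].loc[("overall", "basal"),
                                  ["recall_pct", "dice_all_pct"]])
```

prints

```
n_cases      2.900000e+01
mean_diff   -9.447457e+00
sd_diff      6.431205e+00
t_stat      -7.910821e+00
p_value      1.288848e-08
pearson_r    9.489319e-01
Name: lvedv_ml, dtype: float64
recall_pct      56.321839
dice_all_pct    55.464184
Name: (overall, basal), dtype: float64
```

The LVEDV row recovers the injected under-segmentation as a significant
negative bias of ≈ −9.4 ml (the −0.5 mm radial bias contributes ≈ −4.4 ml;
the rest comes from the cases whose basal anchor slice was dropped) while
the correlation with the expert stays high. The stratified row shows the
dropped basal anchors depressing basal recall and the all-slices Dice;
midventricular rows (not shown) stay at 100%. The same analysis is available from the shell:

```sh
cmrqc simulate --n-cases 29 --seed 7 --outdir sim/
cmrqc compare --expert-dir sim/expert --reader-dir sim/ai --outdir report/
```

which writes the parameter/stratified/equivalence tables as CSV, per-slice
records, candlelight boxplots, position-coloured correlation plots,
Bland-Altman panels and a run-metadata sidecar.

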