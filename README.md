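# wmtex

Texture analysis of brain MR white matter for dementia classification.

Structural MR images of people with Alzheimer's disease (AD), Lewy body
dementia (LBD) and normal controls (NC) can carry diagnostic information in
the *texture* of white matter (WM) and white-matter lesions (WML) even when
lesion volumes do not differ between groups. `wmtex` implements that idea as
a tested, reusable pipeline for neuroimaging researchers: local binary
pattern and local-contrast maps inside WM/WML regions of interest, a
48-feature summary vector per subject, SMOTE rebalancing of imbalanced
cohorts, and nested cross-validated random-forest classification with
wrapper feature selection.

## Method

**Local binary patterns.** For a pixel with gray value `g_c`, sample `P`
neighbors `g_0..g_{P-1}` anticlockwise on a circle of radius `R` (bilinear
interpolation off the pixel grid) and threshold:

    LBP_{P,R} = Σ_p s(g_p − g_c) · 2^p,    s(x) = 1 if x ≥ 0 else 0

The rotation-invariant code is `LBP^{ri} = min_i ROR(LBP, i)` over all `P`
circular bit rotations.  With the uniformity measure `U` (number of
circular 0/1 transitions), the rotation-invariant *uniform* code is

    LBP^{riu2} = Σ_p s(g_p − g_c)   if U ≤ 2,   else P + 1

so uniform patterns are labelled by their count of set bits and all
non-uniform patterns share the miscellaneous label `P + 1`.  The companion
contrast measure is the neighborhood variance
`VAR_{P,R} = (1/P) Σ_p (g_p − μ)²`, rotation-invariant and invariant to
gray-level shifts.

**Features.** Maps are computed slice-wise for three scales — (P=8, R=1),
(P=12, R=2), (P=16, R=4) — inside the ROI; the pooled LBP-code and contrast
distributions are each reduced to mean, SD, variance, median, IQR, Shannon
entropy, skewness and kurtosis: 2 descriptors × 3 scales × 8 statistics =
**48 features per subject**.

**Lesion segmentation.** WML are thresholded slice by slice on FLAIR-like
volumes at `scale_factor ×` the mode of the slice's brain-intensity
histogram.

**Classification.** Imbalanced cohorts are SMOTE-oversampled to the
majority-class size (inside each training partition by default, so no test
information leaks).  A best-first forward wrapper search, scored by the
inner 10-fold-CV macro F-measure of a 10-tree random forest and stopped
after five stale expansions, selects features per outer fold; total accuracy
and per-class precision/recall are reported as mean (SD) over the 10
stratified outer folds.

A synthetic-cohort generator (Gaussian random fields with class-dependent
correlation length, plus spherical lesions) makes every stage testable
without any clinical data.

## Worked example

`examples/02_segment_lesions.py` generates a FLAIR-like volume (mean 100,
texture SD 5) with three lesions at twice the mean intensity and thresholds
it at 1.4 × the per-slice histogram mode:

```
ground-truth lesion voxels: 162
segmented lesion voxels:    162
Dice overlap:               1.000
```

A Dice overlap of 1.0 means the mode-scaled threshold recovered the ground
truth exactly; on noisier contrasts values above 0.9 still indicate close
agreement.  The other example scripts walk through texture maps
(`01_texture_maps.py`), the 48-feature vector (`03_extract_features.py`),
SMOTE balancing of a 57/16/36 cohort to 57/57/57 (`04_smote_balance.py`)
and a full nested-CV run on a two-class synthetic cohort
(`05_nested_cv.py`).

A thin CLI mirrors the stages:

```sh
wmtex simulate --profile paper-imbalance --seed 1 --out cohort/
wmtex run-all --manifest cohort/subjects.csv --out-dir results/ --seed 1
```

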