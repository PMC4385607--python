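# Methods

This note records the modelling conventions, parameter choices and known
limitations of `wmtex`, in the spirit of the model documentation shipped by
mature scientific packages.

## Texture operators

The circular-neighborhood geometry places sample `p` of `P` at
`(−R sin(2πp/P), R cos(2πp/P))` relative to the center pixel, first
coordinate along the slice's row axis, increasing `p` running anticlockwise.
Offsets within 1e−9 of an integer are snapped, so for (P=8, R=1) the four
axis-aligned samples are exact pixel reads while the diagonals are
bilinearly interpolated.  Bilinear interpolation uses the incremental form
`a + fr(c−a) + fc(b−a) + fr·fc(a−b−c+d)`, which is exact on constant and
linear fields; this makes the tie rule (`g_p = g_c` counts as "brighter or
equal", bit 1) and zero contrast behave exactly on degenerate inputs.

The binomial weight of sign `p` is `2^p`.  A variant of the defining sum is
sometimes reprinted with a constant exponent (`2^P` for every term); that
reading cannot produce a unique code per pattern and is not used.

Two counting conventions exist for the uniformity measure `U`:

* **circular** (used by the `riu2` operator, and the standard convention):
  the number of 0/1 transitions around the closed ring, including the
  wrap-around pair — always even; `U(00000011₂) = 2`;
* **written-string** (used in textbook worked illustrations): transitions
  reading the pattern end to end without the wrap term; `U(00000011₂) = 1`,
  `U(10000111₂) = 2`.

Both are exposed (`uniformity`, `uniformity_linear`) and both are tested;
the classifier pipeline only ever uses the circular count, thresholded at 2.

Contrast `VAR_{P,R}` is the *population* variance (divisor `P`) of the `P`
neighbor values, center excluded.

**Invariances.**  LBP maps are exactly invariant to gray-level shifts and
to positive affine intensity transforms (bilinear sampling is linear, so
affine maps commute with it).  Under a general strictly increasing
*nonlinear* transform the ideal operator is invariant, but interpolation
does not commute with nonlinear maps, so sign flips can occur where
`|g_p − g_c|` is comparable to the interpolation curvature error; exact
invariance then holds wherever samples are exact reads (e.g. the
all-integer-offset geometry P=4, R=1).  The test suite asserts the affine
case on the interpolated geometry and the general monotone case on the
exact-read geometry.  Contrast maps are shift-invariant but scale with the
square of any intensity scaling.

**Boundary handling.**  Masked voxels whose sampling disc leaves the slice
are skipped and tallied (`n_skipped`), never padded: padding would
fabricate texture.  Neighbor values are read from the full slice, not
restricted to the mask, so an ROI hugging a strong edge (e.g. the brain
boundary) legitimately picks up that edge's contrast.  Slices are taken
perpendicular to a configurable `slice_axis`, defaulting to the third
volume axis (axial convention).

## Lesion segmentation

Per slice, the threshold is `scale_factor ×` the mode of the brain-voxel
intensity histogram (fixed 256 bins over [min, max]; ties to the lower bin;
a constant slice is its own mode).  Voxels *strictly above* the threshold
are lesion.  Design points the literature leaves open and the choices made:
the comparison is strict (`>`), the mode is computed over brain-masked
voxels only, and slices with fewer than `min_brain_voxels_per_slice`
(default 50) brain voxels produce no estimate and no lesions.  The scale
factor itself is data-dependent and deliberately has **no default**; it was
hand-tuned in the original procedure, and the recommended practice here is
to calibrate it on synthetic volumes with known lesion masks (scale 1.4
achieves Dice ≥ 0.9 at lesion contrast 2.0 in the shipped tests).  The
segmentation is invariant to positive intensity scaling (the mode scales
along) and shrinks monotonically as the scale factor grows.

## Feature summary

"Variation" among the eight statistics is computed as the **variance**
(SD²), not the coefficient of variation, which is undefined for zero-mean
data such as contrast-free constant regions.  LBP codes are summarized
directly as numeric values (mean/median/… of code labels) even though code
labels are nominal — this mirrors the summary-statistic design the pipeline
implements; histogram-of-codes features are intentionally out of scope.
Entropy is base 2, over the empirical label distribution for codes and a
32-bin [min, max] histogram for contrast.  Skewness and kurtosis are the
adjusted (bias-corrected) estimators, kurtosis as excess.  A constant
sample defines SD, variance, IQR, entropy, skewness and kurtosis all as 0.
Distributions are pooled across slices into one ROI-wise collection per
subject before summarizing (per-slice averaging was the alternative; pooling
keeps small ROIs estimable).  Fewer than 8 values in any collection is an
error naming the subject/ROI, because third- and fourth-moment estimates
below that are meaningless.

Feature names follow `{LBP|C}_P{P}_R{R}_{statistic}` in a fixed order
(per scale: LBP block then contrast block), 48 in total.

## SMOTE

Each minority class is raised to the majority count with the classical
interpolation rule `x + u(x_nn − x)`, `u ~ U(0,1)`, neighbors drawn from
the k = 5 nearest same-class rows (Euclidean on the native feature scale —
no standardization, consistent with a pipeline that avoids intensity
normalization).  `k` truncates with a warning for classes smaller than
k + 1.  Placement relative to cross-validation is a correctness issue:
balancing before splitting leaks interpolated copies of test neighbors into
training data, so the default is balancing **inside each outer training
partition**; a `pre-split` mode exists for comparison with analyses that
balanced the whole table first.

## Nested cross-validation and wrapper selection

Outer loop: stratified 10-fold CV (every fold's class proportions within
one instance of the cohort's).  Inner loop, run on each (balanced) outer
training partition: best-first forward subset search starting from the
empty set (merit 0), expanding the best open node by all single-feature
additions, scoring each candidate by the mean macro F1 of a 10-tree random
forest under stratified 10-fold CV, and stopping after 5 consecutive
expansions without a new best subset.  Macro F1 treats a class with no true
and no predicted instances as 0.  Every subset is evaluated at most once;
all subset evaluations share one derived random stream (common random
numbers), so merit comparisons are paired and two subsets presenting
identical data receive identical merits — without this, seed noise
masquerades as improvement on uninformative features.  Improvements must
exceed the incumbent by 1e−10 to count.

The final per-fold classifier is scikit-learn's
`RandomForestClassifier(n_estimators=10)`; inside the wrapper's merit loop
the same 10-tree Breiman procedure (bootstrap + √d feature sampling +
majority vote, ties to the lowest class index) runs as a thin bagging loop
over scikit-learn decision trees, which avoids the ensemble object's
per-fit overhead across the thousands of tiny fits a search performs.  A
test checks the two agree on separable data.

Per-fold metrics: total accuracy `T` = trace/total of the fold confusion
matrix, per-class precision and recall from its columns and rows.  A class
never predicted in a fold has undefined precision: such folds are excluded
from that metric's mean(SD) by default, and an `undefined_as_zero` switch
reproduces the convention of scoring them 0 (some toolkits print
"0.00 (0.00)" for a class that is never predicted).  Summaries are the mean
and sample SD (divisor n−1) over outer folds.

Determinism: one seed drives fold assignment, SMOTE, subset-merit streams,
and all forests; a fixed seed reproduces the full report bit for bit.

## Synthetic cohorts

Volumes are ellipsoidal "brains" (semi-axes 0.45 × shape) with an interior
WM ellipsoid (0.28 × shape); texture is white noise smoothed with an
isotropic Gaussian kernel of width `corr_length` and rescaled so the SD over
brain voxels equals `sigma` exactly, added to the class mean (background 0).
Correlation length is the class-separating control: smoother fields produce
fewer non-uniform LBP patterns, a mechanism the pipeline must detect.
Lesions are spheres (radius 2–4 voxels by default) at `contrast ×` mean,
clipped to the WM region, recorded in a ground-truth mask.  What the
generator does **not** emulate: anatomy, partial-volume effects, bias
fields, scanner noise spectra, or inter-site variation — so passing
calibration tests demonstrates the pipeline's statistical correctness and
sensitivity to texture differences, not clinical performance on real MR
data.

Cohort profiles: the imbalanced design (57 AD / 16 LBD / 36 NC, matching a
realistic dementia cohort) for exercising SMOTE; balanced, null (two
classes, identical parameters) and signal (correlation lengths differing by
a chosen ratio) profiles for calibration.

**Problem sizes used in the shipped calibration tests** (chosen once as
desk-scale study conditions): volumes of 48×48×8 voxels; the strong-signal
cohort uses 30 subjects per class with correlation lengths 1 vs 4 and must
reach mean nested-CV accuracy ≥ 0.9; the null cohort uses 12 subjects per
class and its pooled correct-classification count must fall inside the
central 95% binomial band around chance.

## Known limitations

* 2D slice-wise analysis only; no 3D spherical neighborhoods.
* Tables of real-cohort accuracies cannot be reproduced without the
  original clinical data; the synthetic calibration suite stands in as the
  verifiable counterpart.
* LBP is a local-gradient operator and is noise-sensitive; the `riu2`
  variant mitigates this by collapsing high-transition patterns.
* The wrapper search is greedy best-first; it bounds compute, not
  optimality of the selected subset.
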