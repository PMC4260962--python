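# Methods

This note records the models, conventions and numerical choices behind
`nucmorph`, in the order the pipeline runs, together with what the
synthetic cohorts do and do not establish.

## Segmentation

Nuclear candidates are pixels with hue in [180°, 320°], saturation ≥ 0.15
and value ≤ 0.85 in hexcone HSV. The gate brackets hematoxylin blue-purple
while the value ceiling rejects the bright eosin background (whose hue can
also fall in the magenta range); all three thresholds are configurable in
`PipelineConfig`. Cleanup fills holes (chromatin-sparse nuclear interiors
gate out and must be recovered), then closes with a 2 px disk — small
enough at 0.25 µm/px not to fuse distinct nuclei, large enough to merge
fragments of one nucleus.

Watershed markers are the regional maxima of the Euclidean distance
transform, suppressed within a window of half-width 8 px (≈ the radius of
the smallest in-range nucleus, since the 200 px area floor corresponds to
r ≈ 8 px). Connected maxima plateaus — common on the ridge of an elongated
nucleus — collapse to a single marker, avoiding systematic over-splitting.
Foreground components that end up without a marker are appended as their
own labels so the watershed partitions the cleaned mask exactly. The size
filter keeps areas in the closed interval [200, 4000] px. Labeling uses
4-connectivity; boundary tracing 8-connectivity, so contours stay closed.

## Color channels

Optical density is `OD = −log10((I+1)/256)` per channel: one grey level of
regularization keeps the log finite and makes a fully transmitting pixel
(I = 255) exactly OD 0, which in turn makes the synthetic renderer's
Beer–Lambert forward map exactly invertible up to 8-bit rounding. The
default stain matrix is the standard published H&E OD vector pair
(H ≈ (0.650, 0.704, 0.286), E ≈ (0.072, 0.990, 0.105), rows normalized),
configurable for other stain batches; adaptive stain estimation is out of
scope. Deconvolved concentrations are clipped at 0.

The Lab and Luv lightness channels are both CIE L\* and are computed
through one shared code path (sRGB companding, D65), so the two planes are
bit-equal; both are retained because the 8-channel schema names both.
Texture computation quantizes each channel per nucleus (below); the
`ChannelStack` also carries per-ROI min–max 8-bit views of every plane,
since BR and OD are unbounded.

## Shape features (12)

Area is the pixel count. Perimeter uses the 4-direction Crofton
line-intercept estimator: it is exactly invariant under 90° rotation and
unbiased for smooth outlines, at the cost of slight undershoot on convex
digital shapes — circularity `4πA/P²` is therefore clipped at 1 (a digital
disk of radius 30 measures ≈ 0.995). Equivalent spherical perimeter is
`2√(πA)`, the perimeter of the circle with the region's area. The moment
ellipse takes its axis directions from the second-central-moment
eigenvectors and is rescaled so its area equals the region's, which makes
roundness `4A/(π·major²)` equal `minor/major` exactly for true ellipses;
collinear regions have the minor axis floored at 1 px. The bounding
rectangle is axis-aligned. Solidity divides by the pixel count of the
convex hull image (not the hull polygon area, which would exceed 1 on
rectangles). Feret's diameter is the maximum pairwise distance over
convex-hull vertices of pixel centers.

## First-order features (5 × 8 = 40)

Computed on the float channel planes within the nucleus mask: mean, median
(mid-mean for even n), variance (n−1), moment skewness `m₃/m₂^{3/2}` and
excess kurtosis `m₄/m₂² − 3` with 1/n central moments; a constant region
is assigned skewness 0 and kurtosis 0. The dispersion column is named
`Variance` to match the historical feature-naming convention
(`Mean_Variance_Red`, …); it is the square of the sample SD, so either
parameterization is a one-line change. Masks below 4 px (impossible after
the size filter) are rejected.

## Texture features (18 × 8 = 144)

Masked values are linearly binned into N_g = 32 levels per nucleus
(min–max; constant regions map to level 1). 32 levels keeps the matrices
of 200–4000 px nuclei adequately populated while preserving contrast
resolution; it is configurable.

GLCM: for each of the four displacement offsets (0,1), (1,0), (1,1),
(1,−1), pairs with *both* pixels inside the mask are counted in both
orders, each direction's matrix is normalized to sum 1, and the matrices
are averaged. Directions with no valid pair are skipped from the average
(they cannot be normalized); if no direction has a pair the nucleus
receives the constant-region limits (energy 1, entropy 0, inertia 0,
IDM 1, remaining statistics 0). The eight statistics are energy, entropy
(base 2; the base is a constant factor absorbed by standardization),
inertia, inverse difference moment, correlation, cluster shade, cluster
prominence, and the classic marginal-form Haralick correlation. For a
symmetric normalized matrix the two correlations coincide algebraically;
both columns are kept to preserve the 8-statistic schema and the equality
is asserted in tests rather than deduplicated.

GLRLM: maximal runs of equal level along in-mask collinear sequences, with
mask gaps terminating runs; the four per-direction matrices are
zero-padded to a common maximum run length and averaged entrywise
(mirroring the GLCM treatment of directions). The ten run statistics use
1-based level and length indices, so every division is safe.

Both builders are verified against naive enumeration oracles over a sweep
of small masks, exactly to 1e-12.

## Patient summary (392)

Mean and n−1 SD of each per-nucleus feature, pooling nuclei across the
patient's ROIs with equal weight per nucleus (no ROI weighting). Patients
with fewer than two nuclei are excluded with a logged reason, since the SD
is undefined.

## Classifier

The objective is the mean logistic negative log-likelihood plus `λ‖w‖₁`
with an unpenalized intercept. The path over 100 log-spaced λ from
`λ_max = max_j |Xᵀ(y−ȳ)|/n` down to 0.01·λ_max is solved by accelerated
proximal gradient (FISTA) with warm starts, wrapped in an active-set
strategy: each λ is solved on the currently nonzero or KKT-violating
columns, then the Karush–Kuhn–Tucker conditions are re-checked on all
columns and violators are added until none remain. The soft-threshold
step produces exact zeros, and at λ ≥ λ_max the null model is returned
exactly by the KKT bound. Because FISTA's step size treats the flat
intercept direction poorly, the intercept is polished by one-dimensional
Newton steps after each solve. Path fits stop when the maximum coefficient
change is ≤ 1e-7 (capped at 2000 iterations per subproblem); the final
refit at the selected λ uses 1e-8 with a much higher cap. Small instances
agree with an independent scipy convex solver to better than 1e-5 per
coordinate.

Cross-validation is stratified k-fold (default 9) with folds fixed by the
seed; each training split must contain both classes (re-seeded attempts,
then an error). Per λ the held-out probabilities are pooled across folds
before computing the ROC (the per-λ "CV AUC"); per-fold AUCs provide the
standard error used by the 1-SE rule. Ties in the AUC argmax break toward
the larger λ (the sparser model). AUC is the Mann–Whitney statistic with
ties counted ½, computed by a descending-score sweep. Standardization is
z-scoring per dataset; a fitted model stores the parameters and external
datasets are standardized dataset-locally at prediction time,
matching the per-dataset convention used at training. Ablation re-runs
the entire CV selection on the three feature-class subsets (textural 288,
morphological 24, intensity 80 columns) and on the eight per-channel
subsets (46 columns each).

## Synthetic cohorts

The generator plants non-overlapping ellipses (equivalent radius drawn per
class, aspect ratio uniform, orientation uniform) whose areas are
guaranteed inside the size filter, assigns hematoxylin OD inside nuclei as
a base level modulated by a Gaussian-smoothed noise field (the "chromatin"
texture, with class-specific amplitude and correlation length), low eosin
inside nuclei and a mildly textured eosin background, and renders RGB by
Beer–Lambert through the same stain matrix the analysis deconvolves — so
stain recovery is an exact round-trip oracle up to quantization.

Defaults encode a two-institution study shape: training 36 benign-like +
80 malignant-like patients, validation 31 + 20, two 224×224 px ROIs of 16
nuclei per patient. The malignant-like class has larger mean radius
(15 vs 11 px), larger radius spread (2.5 vs 1.2 px, pleomorphism), higher
aspect ratios, and stronger, coarser chromatin texture — the axes a
pathologist would recognize, at deliberately strong contrast; `weak` and
`none` presets shrink or remove the contrasts. The generator does not
model stroma, ducts, necrosis, touching-nuclei clusters, out-of-focus
blur, or stain variation between datasets (an optional stain-perturbation
test exercises robustness separately). Passing end-to-end tests therefore
establishes that the machinery — segmentation, the 196/392 feature
contract, selection, fixed-model transfer — is correct and
well-calibrated on images whose generative process matches the pipeline's
assumptions; it does not establish classification accuracy on real
histology.

## Degenerate inputs and numerical conventions

Empty masks propagate as empty label maps; nuclei below 4 px are excluded
from feature extraction with a log line; constant channels give zeroed
z-scores (flagged), skewness/kurtosis 0 and the constant-texture limits;
zero-variance columns are flagged by the standardizer and contribute
nothing to the model. All randomness (cohort generation, CV folds)
descends from the single config seed; reruns are byte-identical.

## Known limitations

The null-cohort "CV AUC" is a maximum over the λ grid taken on one finite
cohort, and is therefore upward-biased under the null twice over: grid
selection, and the realized class differences of a 36-vs-80-patient draw
(per-feature SD ≈ √(1/36+1/80) ≈ 0.2σ however many nuclei are measured
per patient, and the lasso finds the largest of 392 columns).  Measured
over replicate zero-effect cohorts the headline CV AUC averages ≈ 0.6 and
individual cohorts reach ≈ 0.75; the stable null diagnostic is the mean
over permutation replicates, not a single cohort's value. The HSV gate is tuned to
hematoxylin-range rendering and will need re-tuning for heavily faded or
over-stained slides. Watershed merges deeply overlapping nuclei whose
distance transform has a single maximum. Crofton perimeter slightly
undershoots on very small regions, which the circularity clip masks but
does not remove.
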