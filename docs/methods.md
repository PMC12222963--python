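# Methods

`glomkit` implements the computational stages that surround a
multi-class glomerulus segmentation network for IgA nephropathy (IgAN)
biopsy slides: overlap-tiled inference aggregation, watershed instance
separation, lesion-class-specific morphometry, object-level evaluation,
and morphometry-driven prognostic classification.  The trained network
itself is out of scope; it is replaced by a predictor contract with two
reference implementations, so every stage is exercised end-to-end on
synthetic fixtures.

## Coordinate and resolution conventions

Pixels are 0-based `(row, col)`; all windows are half-open `[lo, hi)`.
Every raster carries a microns-per-pixel (mpp) value.  The working
resolution is fixed at 1.0 um/px: scanners producing 0.25 or 0.21 um/px
native scans are both area-average downsampled to the same physical
resolution, so morphometric features are scanner-independent.
Upsampling is refused — it would invent image content.

Masks are stored as a single label grid (0 = background, 1–5 = no
lesion, global sclerosis, segmental sclerosis, crescent, ischemic
change).  Disjointness of the five class channels therefore holds by
construction; the 5-channel binary form exists only at the model
boundary.  A glomerulus carries exactly one lesion label.

## Tiling, TTA and stitching

Slides are covered by 512 x 512 windows at 50% overlap (stride 256).
The final row/column window is clamped so its far edge meets the slide
edge — duplicated coverage is harmless under mean aggregation, whereas
padding would fabricate tissue.  Every interior pixel is covered by
exactly four windows.  Patches without any glomerular pixel are
discarded; class balancing keeps no-lesion-only patches with a
configurable probability and replicates patches containing minority
lesion classes.

Test-time augmentation uses an enumerable variant set (default: the six
axis-aligned geometric transforms at native intensity plus identity at
intensity x0.9 and x1.1) with per-pixel mean fusion.  Overlap fusion at
stitch time is likewise the arithmetic mean of channel probabilities;
max-voting was rejected because it inflates boundary artifacts.
Hardening assigns the argmax channel where the maximum probability
reaches the threshold (default 0.5), ties breaking to the lowest class
index.

The predictor contract is `(patch_pixels, patch_ref) -> (h, w, 5)`
probabilities in [0, 1].  The ground-truth oracle predictor is
window-addressed (it reads a slide-level mask, optionally corrupted by
per-instance class confusion, boundary erosion/dilation and clipped
Gaussian probability noise); the colour-threshold predictor is purely
pixel-driven.  Geometric TTA inversion is exact only for pixel-driven
predictors, which is the case that matters in practice.

## Instance separation

Connected over-segments (touching glomeruli merged into one region) are
split by marker-controlled watershed on the Euclidean
distance-to-background transform of the union support across classes.
Glomerulus centres are local maxima of that transform; the watershed
floods its negation.  Separation runs on the union support rather than
per class because merged neighbours can differ in lesion class; each
separated region is then re-assigned the majority mask label, and its
confidence is the regional mean of the winning channel probability.

Markers are depth-filtered (h-maxima, default depth 1 px) and then
greedily suppressed within a minimum separation (default 15 px ~ 15 um),
so shallow secondary peaks inside an elongated glomerulus do not split
it while genuinely bimodal distance maps do.  The distance map is
Gaussian-smoothed (sigma 2 px) first.  Regions below 300 px are merged
into their largest adjacent region or dropped when isolated.  All four
values are configuration-exposed; the defaults were tuned on the
synthetic suite.

## Morphometry

Per-instance features follow standard region-props definitions: area
(pixel count x mpp^2); major/minor axis lengths of the
moment-equivalent ellipse; eccentricity sqrt(1 − (minor/major)^2);
solidity (area over convex-hull area); compactness P^2/(4 pi A) with the
perimeter P estimated by the 4-direction Crofton formula (nearly
unbiased on smooth digitised boundaries, so a disk scores ~1); and
roundness 4A/(pi major^2).  Degenerate regions (single pixels, collinear
sets) fall back to bounding-box axes and are flagged.

The slide-level vector holds, per class, the count ratio, area ratio and
the mean of the six shape features over that class's instances, plus one
global glomerular-area-over-tissue-area ratio: 41 features.  Absent
classes are zero-filled and accompanied by five explicit per-class
presence flags, so a downstream model can distinguish "no crescents"
from "tiny crescents".  Averages are taken over glomeruli within a
slide; cohort-level displays average over slides.

## Evaluation

A prediction is a true positive when it covers at least 50% of a
ground-truth instance of the same class (coverage relative to the
ground-truth region, not IoU; an IoU flag exists for comparison
studies).  Matching is greedy in descending prediction confidence, each
prediction claiming the unclaimed ground truth with the largest
coverage.  On disjoint ground truth this greedy scheme attains the
optimal assignment (verified against exhaustive search).

Average precision pools predictions across slides, ranks by confidence
and integrates the precision–recall sweep with all-point interpolation.
Dice is micro-aggregated over pixels across slides.  Class-level scores
are combined by ground-truth-count weighting, which reproduces the
published internal-validation weighted AP row (0.795) from its per-class
values; the published external weighted AP and the weighted DSC rows are
not reproducible from their printed per-class values by count weighting
(the original weighting there is unstated), so only the internal AP row
is used as an anchor.  Confidence intervals are percentile bootstrap
(B = 1000) resampling slides.

## Prognosis

The outcome event is the first follow-up time with eGFR below 50% of
baseline, eGFR < 15 mL/min/1.73 m2, or kidney replacement therapy;
otherwise censoring at last follow-up.  Patients with under six months
of follow-up or no usable follow-up are excluded with machine-readable
reasons.  Time-to-event modelling is deliberately excluded; labels are
binary.

Five feature sets (image; clinical; image+clinical; IIgAN-PT variables;
image+IIgAN-PT) feed three classifier families with fixed, documented
hyperparameters: XGBoost (300 trees, depth 3, learning rate 0.1),
random forest (500 trees) and L2 logistic regression (C = 1) on
standardised inputs.  No event-class reweighting is applied.  Missing
values are imputed by the training-set median with indicator columns.
The IIgAN-PT variable list (age, eGFR, MAP, UPCR, Oxford M/E/S/T, RASB,
immunosuppression) is a plain editable list; the published risk
equation itself is never computed.  Test AUC uses the Mann–Whitney
identity (equal to the trapezoidal ROC area); its 95% CI and all model
comparisons use DeLong's structural-components method.  Feature
importances are impurity gain for trees and absolute standardised
coefficients for the logistic model.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not PAS texture.  A slide is an elliptical tissue core containing
ellipse-shaped glomeruli with low-frequency radial noise (harmonics
k = 2–4, amplitude <= 5%), keeping analytic shape expectations
checkable.  Default geometry: 18 glomeruli of 35–75 um mean radius on a
1536 x 1536 um slide, giving a glomerular-to-tissue area fraction near
10%.  Class mix defaults to the prevalences of a large annotated IgAN
training cohort (NL 0.706, GS 0.201, SS 0.059, CR 0.019, ISC 0.015).
Per-slide class weights are drawn from a Dirichlet centred on that mix
(concentration 3), reproducing the large between-patient spread of
lesion burden observed in real cohorts (GS count-ratio sd ~0.2); the
jitter can be disabled for i.i.d. sampling checks.  Each class renders
with a distinct mean colour so a colour-threshold predictor can
succeed.

A configurable fraction of glomeruli is placed deliberately touching a
neighbour, producing the merged mask components watershed separation
exists for.  Touching partners are drawn round-ish (axis ratio
>= 0.85), of comparable radius, never chained onto an already-merged
instance, and at centre separation of at least 1.2 x the pair's mean
radius: these constraints keep instance identity geometrically
well-defined (no engulfed or chained blobs), which is the regime in
which exact count recovery is a meaningful test of the separation
stage.

The cohort generator draws clinical variables from marginals matching a
real IgAN cohort (age 34 +/- 19, eGFR 94 +/- 46, ~55% male, Oxford
score marginals, etc.), independent of outcome.  The binary event is
Bernoulli with log-odds `base + beta x GS_count_ratio` (defaults
-1.9 + 2.0 x ratio, landing near the ~18% adverse-outcome prevalence of
an internal cohort).  eGFR trajectories are piecewise linear with one
point per six months and cross 50% of baseline exactly when the event
fired, the minimum structure needed to exercise the outcome labeller.
The closed-form expected AUC of the Bayes-optimal score is computed
from the sampled event probabilities and upper-bounds any fitted
model's expected test AUC.

What passing on synthetic data does **not** show: robustness to PAS
stain variation, annotation noise, texture-dependent segmentation
errors, or correlated clinical confounding — none of which the
generator models.

## Problem sizes

The test suite and the acceptance script run the pipeline at reduced
problem sizes chosen to keep the full run deskside: 320–512 px slides
with 6–10 glomeruli of 14–36 um radius for pipeline checks, 200 slides
for the watershed recovery rate, and 1000 patients (500 train / 500
test) for prognostic signal recovery.  All sizes are parameters; the
defaults in the library reflect the full-scale geometry above.

## Known limitations

* Ground-truth recovery guarantees hold only for the identifiable-pair
  geometry described above; deeply engulfed glomeruli are counted as
  their host.
* The oracle predictor is window-addressed, so geometric TTA is a
  no-op guarantee only for pixel-driven predictors.
* DeLong p-values assume asymptotic normality; with very few events the
  bootstrap CI option is preferable.
* No WSI pyramid decoding: inputs are plain rasters with mpp metadata.
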