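# Methods

## The scoring problem

The Psoriasis Area and Severity Index (PASI) summarises psoriasis
severity over four body regions — head, trunk, upper limbs, lower limbs.
A rater assigns each region an area band A ∈ {0..6} (the binned
percentage of that region's skin that is involved: 0%, <10%, 10–29%,
30–49%, 50–69%, 70–89%, 90–100%) and three ordinal severities in
{0..4}: erythema E (redness), induration I (plaque thickness) and
desquamation D (scaling).  The total is

    PASI = Σ_r  w_r · A_r · (E_r + I_r + D_r),
    w = 0.1 (head), 0.3 (trunk), 0.2 (upper limbs), 0.4 (lower limbs),

with range 0–72.  Totals are reported to one decimal, rounding half
away from zero, matching clinical score tables.  Severity strata used
throughout are low (PASI ≤ 5), medium (5 < PASI ≤ 10) and high
(PASI > 10).

This package estimates the sixteen subscores from photographs — several
images per region per visit — and composes the total, then evaluates
the estimates the way a longitudinal severity study would: mean
absolute error of the total, exact-match accuracy of the subscores
(7-label for area, 5-label for E/I/D), error stratified by true
severity, and pairwise trend consistency across visits.

## Model

Per region, N images are each passed through a convolutional encoder
whose stages (3×3 convolutions, stride 2) carry squeeze-and-excitation
channel gating.  Two backbone plans exist: `small_se` (three stages,
16/32/48 channels — the desk-scale default) and `deep_se` (five stages,
16/24/40/80/112 channels, following the EfficientNet-B0 stage
silhouette).  A parallel 1×1-convolution branch off the final feature
map emits a single-channel attention map squashed to [0,1] by a
sigmoid.  The attention map multiplies the visual feature map
elementwise before global average pooling, so feature content away from
lesions is suppressed; the branch is supervised with per-cell binary
cross-entropy against heatmap masks rasterized from lesion bounding
boxes (exact area-average downsampling to the attention grid, so a
cell's target equals the covered fraction of its receptive area).

The N pooled image vectors are fused by concatenating their elementwise
maximum and mean (either half can be ablated).  Fusion is symmetric in
the input order, which makes the whole pipeline exactly
permutation-invariant at inference time.  A learned region-identity
embedding is added to the fused vector — one network serves all four
regions (configurable; per-region training just means four nets).  A
small dense trunk feeds two heads per subscore: a regression scalar
(smooth-L1 loss, the final output) and classification logits (softmax
cross-entropy; 7 labels for area, 5 otherwise).

The cross-teacher term couples the heads.  With p = softmax(logits) and
μ = Σ_k k·p_k:

    L_cross = smooth_l1(regression, sg(μ))
            + CE(logits, label = clamp(round(sg(regression)), 0, K−1)),

where sg(·) is a stop-gradient: the classifier teaches the regressor
through its expected label and the regressor teaches the classifier
through its rounded pseudo-label, but neither term backpropagates into
its own teacher.  The literature this idea descends from gives no
closed formula; the form above is this package's own definition and is
frozen by tests against an independent reimplementation.

Predicted integer subscores are the regression outputs clamped to the
legal range and rounded half away from zero (for a pure-classification
configuration, the argmax labels instead).  The four predicted region
assessments compose to the visit's PASI by the exact formula above.

## Training

The loss is L = w₁·L_reg + w₂·L_cls + w₃·L_attn + w₄·L_cross with unit
weights by default; header modes switch off the terms that do not
apply.  The optimizer is Adam at learning rate 1e-3 (no schedule, no
early stopping; the best-validation-MAE parameters are retained).
These are desk-scale defaults chosen once, not tuned per experiment.
Training-time geometry is a seeded random crop of 70–100% of each
dimension followed by bilinear resize to the model size; lesion boxes
are transformed through the same crop so attention targets stay
aligned.  Evaluation geometry is a deterministic full-frame resize.
When a region has more images than the configured view count a seeded
subsample is taken; with fewer, all are used.  Everything downstream of
the config seed is deterministic in a single-threaded run, and batches
are bucketed by view count so stacking is rectangular.

All tensor math runs on a small in-package reverse-mode autodiff engine
over float64 numpy arrays (convolution by im2col, max/mean reductions,
embedding lookup, the three losses).  Every op's gradient is checked
against central finite differences in the unit tests.

## Color normalization

Clinical photographs vary strongly in illumination, so an automatic
color equalization (ACE) step is available ahead of the encoder: for
each channel, every pixel accumulates sat(slope·(I(p)−I(j)))/d(p,j)
over a subsampled reference grid j (saturation clips to [−1,1],
d is Euclidean pixel distance, slope defaults to 5, reference grid
capped at 4096 pixels), and the response is rescaled per channel to
span [0,255]; a zero-variance channel maps to mid-gray.  Because only
pixel differences enter, adding a constant offset to a channel cancels
exactly — the property that removes global lighting shifts.  The
original algorithm family has several parameterizations; slope and
grid stride are config-exposed rather than fixed.  ACE is off by
default in desk-scale training because the synthetic generator's
lighting jitter is mild; enable it for real photographs.

## Synthetic cohorts

The generator exists so every downstream stage is testable without
clinical data.  It renders elliptical, non-overlapping plaques on a
skin-tone field; each PASI subscale maps to exactly one knob:

| knob (∈[0,1])       | rendering                      | ground truth            |
|---------------------|--------------------------------|-------------------------|
| coverage_fraction   | plaque pixel fraction (±2 pts) | area band of 100·f      |
| redness             | interior shift toward red      | E = clamp(⌊5x⌋, 0, 4)  |
| speckle_density     | white speckle overlay          | D = clamp(⌊5x⌋, 0, 4)  |
| border_shading      | darkened border ring           | I = clamp(⌊5x⌋, 0, 4)  |

Placement is rejection sampling (≤1000 attempts, then retries under
derived sub-seeds): each candidate ellipse targets a share of the
remaining coverage deficit; overshoots are trimmed by bisecting the
radius into the ±2-percentage-point tolerance band.  Plaques may be
clipped by the frame — without that, non-overlapping ellipses cannot
reach the 90–100% area band.  Boxes are tight, 0-based, half-open
(x0,y0,x1,y1).  All views of a region share plaque layout, speckle
pattern and skin texture (it is the same skin); each view applies an
independent seeded lighting/color jitter.  Cohorts are bit-reproducible
from one integer seed.

Cohort sampling draws a severity band per visit from a configurable
low/medium/high mix (default 0.50/0.28/0.22, the strata proportions of
a 429-visit follow-up cohort: 214/119/96), then rejection-samples
subscores whose composed PASI lands in that band, and finally inverts
the subscores into knob values drawn strictly inside each band so
rendering tolerance cannot flip the ground truth.  Each patient's drawn
bands are sorted from worst to best across visits — an improvement
trend with real pairwise signal that leaves the marginal band
proportions untouched.  Splits are per patient, 70/15/15.

What the generator does *not* emulate: body pose and anatomy, camera
optics, hair/clothing occlusion, skin-tone diversity, annotation noise
and inter-rater disagreement, and the correlation structure of real
lesion morphology.  Passing desk-scale tests therefore demonstrates
that the architecture and losses can extract these four visual factors
and compose them correctly — not clinical-grade accuracy on
photographs.

## Evaluation

MAE is the mean absolute difference of composed totals.  (One published
description mixes up "squared difference" wording with an absolute
distance definition; the implemented metric is the mean absolute
error, matching the headline tables.)  Subscore accuracy is exact label
match.  Trend consistency enumerates all C(n,2) unordered visit pairs;
pairs with tied reference scores carry no ordering information and are
excluded from the denominator, and a predicted tie on a strictly
ordered pair counts as incorrect (the conservative reading of a binary
success rule; a Kendall-style half-credit policy is available).  Gap
strata are half-open intervals on the real-valued reference gap,
(0,5], (5,10], (10,∞), mirroring the integer labels "0–5 / 6–10 / >10"
of published gap tables.  The statistic is invariant under strictly
increasing transforms of the predictions.

## Numerical choices and degenerate inputs

- Score arithmetic runs in exact decimal; rounding is half away from
  zero at one decimal for totals, at integers for subscores.
- Composition requires exactly one assessment per region; missing or
  duplicate regions are structural errors, out-of-range subscores are
  domain errors with row numbers when read from CSV.
- `trend_consistency` with fewer than two usable pairs returns an
  explicit insufficient-pairs result rather than a number.
- A zero-variance channel in ACE returns mid-gray; zero-area lesion
  boxes are ignored with a warning; boxes outside the frame are errors.
- Max-reduction gradients split equally across ties.
- Checkpoints are single `.npz` files carrying parameters, full config
  and seed; predicting from a missing checkpoint is an explicit error,
  never silent random output.

## Problem sizes used in the shipped experiments

The parameter-recovery experiment trains on a 200-patient cohort
(70/15/15 split) at 64×80 resolution, 3 views per region, for 10
epochs — about three minutes on one CPU — and is expected to reach a
validation total-PASI MAE below half of the constant train-mean
baseline (typical run: ≈1.8 vs ≈8.8), area-band accuracy well above
the 1/7 chance level, and positive Spearman correlation between
predicted erythema and the generator's redness knob.  The ablation
demonstration runs the fusion and output-head grids on a 16-patient
cohort at 32×40 for 2 epochs; it checks table structure and finiteness,
not that desk-scale rankings reproduce clinical ones.

## Known limitations

- The backbone is EfficientNet-B0-shaped, not EfficientNet-B0: no
  ImageNet pretraining, depthwise convolutions or compound scaling.
- The autodiff engine is single-threaded float64 numpy; it is exact and
  deterministic but not fast — full-scale 800×1024 training is out of
  reach, which is why the paper-fidelity image size is config-exposed
  but experiments run at desk scale.
- Four published worked-table rows are internally inconsistent with the
  PASI formula (by 0.1 up to 6.9 points); they are excluded from golden
  tests rather than "fixed", and the formula is not bent to match them.
- Clinical performance numbers from the private 14,096-image dataset
  are not reproducible here and are not claimed; the substituted
  acceptance properties (permutation invariance, oracle equivalence,
  perfect/reversed trend extremes, transform invariance, synthetic
  parameter recovery) are what the test suite actually verifies.
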