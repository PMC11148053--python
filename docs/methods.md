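# Methods

## Problem and model

Total-body melanoma screening asks which of a patient's lesions deviate from
that patient's own nevus pattern (the "ugly duckling" sign). The quantity the
package computes is purely relative: given per-lesion embeddings
`e_1..e_n` for one patient, the reference appearance is the coordinate-wise
median `m = median_i(e_i)` (midpoint of the two central values for even n),
the raw outlierness is the cosine distance `d_i = 1 − cos(e_i, m)`, and the
reported UD score is min-max normalized per patient,
`s_i = (d_i − min d) / (max d − min d)`; when all distances coincide every
score is 0 rather than NaN. Ranks are assigned by descending score with
lesion id as a deterministic tie-break, and the top 10 are proposed.
The coordinate-wise median was chosen over a medoid (which is exposed as an
option) because it is the standard robust location estimate and is stable
when no single lesion is central; the median is taken on raw embeddings and
normalization happens only inside the cosine.

## Detection and tiling

Wide-field images are decomposed into square tiles (default 1280 px, the
resolution a wide-field lesion detector consumes) with a configurable
overlap fraction (default 0.2). Tile grids use a regular stride with the
last row/column shifted inward so the detector only ever sees real pixels;
images smaller than a tile yield one image-sized tile. Per-tile detections
are remapped to global coordinates and merged by greedy NMS: boxes are
visited in decreasing confidence (ties broken by position), and a box is
kept iff its IoU with every kept box is ≤ 0.10. The low threshold reflects
the geometry of the task — distinct lesions essentially never overlap, so
any appreciable overlap indicates a duplicate from the overlap zones.
Detections below 20% confidence are then dropped (boundary kept at
equality).

The built-in detector is classical: the grayscale tile is binarized at a
ladder of thresholds (0.25–0.75, step 0.05), connected components are kept
when their area is in [20, 20 000] px² and circularity `4πA/P² ≥ 0.25`,
components persisting across levels are grouped by center proximity, and
the group's persistence fraction is its confidence. A local-contrast gate
(group interior must be ≥ 0.08 grayscale units darker than its immediate
surround) rejects blobs produced by illumination structure rather than
pigment: a lesion is locally dark even inside a shadow, a shadow interior is
not. These defaults are fixture-driven for the phantom generator's scale;
they are not a learned detector and make no claim of clinical detection
performance. Learned single-class backends plug in through a detector
contract whose configuration records the recipe such a backend should
honor (single class, KNN-derived anchor aspect ratios, channel
normalization disabled, raised box limit, NMS deferred to the merge stage);
the package does not execute any deep detector itself.

## Illumination filter

The illumination feature is the mean grayscale (Rec. 601 luma) intensity of
a crop's frame ring — the outer band of pixels, default width 10% of the
shorter crop side, assumed to show surrounding skin because detector boxes
include a margin. Per patient, the feature's mean and population standard
deviation are estimated in one pass (no trimming) and lesions strictly
below `mu − 2 sigma` are excluded. Population rather than sample SD and the
strict inequality are conventions fixed by the tests; with `sigma = 0`
nothing is flagged. A robust variant (median / scaled MAD) is exposed for
heavily contaminated patients but is not the default, keeping the rule
minimal. The filter is strictly per patient: shadowing is a property of one
acquisition, not of skin in general.

## Patch preparation

Rectangular crops are padded to square — never anisotropically resized —
with a constant equal to the per-channel mean of the frame-ring pixels
(skin is strongly chromatic, so a scalar pad value would introduce a false
color edge); the odd remainder goes to the bottom/right, and the operation
is idempotent. Square crops are then resized bilinearly to the profile's
patch size (224 at full scale). Lesions are normally smaller than the
target, so this is an upscale; larger crops are downscaled with a logged
warning since leaving them unresized would break the fixed input contract.

## Per-patient self-distillation embedder

One embedding model is trained from scratch per patient on that patient's
patches only (minimum 12 — below that the multi-view batch statistics
degenerate). This isolation is the core bias-avoidance property: no other
patient's lesion statistics can leak into the representation, and tests
assert it structurally (training never reads another patient's data).

The trainer follows the self-distillation recipe: student and teacher share
an architecture; the teacher is an exponential moving average of the
student (momentum 0.996); teacher outputs are centered (EMA center,
momentum 0.9) and sharpened at temperature 0.04, student outputs at 0.1;
the loss is the cross-entropy between teacher distributions on global views
and student distributions on all other views of the same patch. Per patch
and epoch, 2 global views (scale 0.4–1.0 of the patch area) and 4 local
views (0.1–0.4) are built; every view passes brightness jitter (±20%,
counteracting residual uneven illumination), random resized crop, and
per-channel color jitter whose strength is the 0.04 base multiplied by 10
(capped so factors stay positive). The tenfold color-jitter strength makes
chromatic deviation — clinically the strongest outlier cue — the dominant
axis of the learned invariance structure; the multiplier scales the jitter
strength parameters, not pixel values. No pretrained weights are ever
loaded.

The network is a small multilayer perceptron over bilinearly downsampled
view pixels (default 16×16×3 input, 256 hidden units, 64-d backbone output,
64-d projection head), implemented directly in numpy with manual
backpropagation and Adam. This backbone was chosen so that a patient trains
deterministically in seconds on one CPU core; the architecture is a
package design decision, and the estimator contract (fit on patches,
transform to teacher-backbone embeddings) is what downstream stages depend
on, not the network family. Inference applies only the resolution
preprocessing — no augmentation — and reads the teacher backbone before the
projection head, the standard representation for self-distilled models.

Training stops by ranking stability: checks run every
`check_interval_epochs` from `min_epochs` on, comparing the current top-10
UD ranking (order-sensitive, ties broken by lesion id) with the previous
check and stopping at the first identical pair; `max_epochs` is a hard cap.
The full-scale profile uses 200/300 epochs with checks every 10; the
desk-scale profile (64 px patches, 20/30 epochs, checks every 2) ships for
CPU-bound test runs. Consecutive-check comparison (rather than stability
over several checks) is the minimal reading of "no longer changes" and is
fixed by tests. Non-finite losses abort with a diagnostic rather than
producing silent garbage.

A deterministic handcrafted-feature embedder fulfils the same estimator
contract for training-free runs: per patch it measures mean lesion RGB, RGB
spread, border contrast, area fraction, eccentricity and log axis
elongation of the thresholded lesion mask, fits per-patient center/scale,
and emits robust z-scores plus a constant anchor coordinate. The anchor
aligns the median embedding with it, so cosine distance from the median
grows monotonically with normalized feature deviation — the same outlier
geometry the scorer expects from the learned embeddings.

## Rater-study metrics

The reference standard is the majority selection of the most experienced
dermatologist group: lesions picked by at least 2 of the 3 experts,
computed from unassisted records only. All selections are truncated to
their first 20 picks after removing poorly illuminated lesions; sensitivity
is `TP/(TP+FN)`; an empty reference makes the value undefined and the image
is skipped, never counted as zero (zero-imputation would bias group means).
Top-u AI sensitivity treats the AI's u highest-ranked lesions as the
selected set against one participant's picks; picks the detector never
found remain in the reference as false negatives. Confidence change is the
per-participant, per-image difference (assisted − unassisted), averaged;
experts' agreement with their own majority is computed with the stated
2-of-3 rule, leave-self-in. Participant-drawn boxes are matched to detected
lesions greedily by IoU (one-to-one, minimum 0.3) — a library cannot
reproduce manual data cleaning, so unmatched boxes are dropped with a
warning. The occasional image where fewer than 10 lesions were highlighted
is handled by per-patient top-k overrides.

## Phantom generator

The generator emulates the structural features the method depends on, not
photorealism: a skin-tone background with a smooth cosine illumination
gradient and mild sensor noise; elliptical shadow regions that
multiplicatively darken everything inside them (so shadowed lesions carry
genuinely darker frames); lesions as soft-edged rotated ellipses with
log-normal pixel areas (median ≈ 148 px², right-tailed like real
patient-wise lesion-size distributions), placed by rejection sampling with
a minimum center gap; and planted outliers displaced along interpretable
axes — color (toward dark red, 3× the base color spread by default),
eccentricity, and size — so effect size is one dial. Default conditions are
100 common + 5 outlier lesions on a 2048×1024 image, exercising multi-tile
behavior at desk scale. Synthetic raters pick outliers and common lesions
with group-specific probabilities (experts ≈ 0.90/0.03 down to students
0.60/0.15), order them outlier-first with noise, and draw confidences from
group-specific distributions over the 1–5 scale; the cohort layout is
4/2/3/2/6 across the five experience groups. Everything is bit-reproducible
per seed.

What the phantoms do not model: hair, tattoos, anatomical curvature,
camera vignetting, true nevus texture. Passing the phantom-based tests
therefore demonstrates the pipeline's internal correctness and the
method's outlier-recovery behavior under controlled effect sizes — not
clinical detection or ranking performance on real skin.

## Numerical and determinism choices

Pixel values are floats in [0, 1] package-wide; coordinates are 0-based,
half-open, origin top-left. Cosine distances are clamped to [0, 2] against
floating-point noise; zero vectors and empty matrices are rejected rather
than silently scored. NMS ties and ranking ties have deterministic
tie-breaks so runs are reproducible to the byte. Every stochastic stage
derives its seed from the run's global seed (per-patient seeds via a hash
of patient id), manifests contain no timestamps, and rerunning a pipeline
with the same configuration and seed reproduces score tables and manifests
bit-identically.

## Problem sizes in the shipped checks

The test-suite and the acceptance script run the full pipeline on
default-condition phantoms (105 lesions each) with the desk-scale profiles:
10 seeds per embedder for recovery checks, 6 + 3 patients in the acceptance
script, 20 small phantoms for tiling closure, 10⁵ draws for the two-sigma
tail, and 100 seeded trials for planted-outlier recovery in score space.
These sizes were chosen so the complete evidence chain runs on a single CPU
core in a few minutes while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

The built-in blob detector is a test-scale stand-in, not a clinical
detector; hair and tattoo robustness are out of scope. The embedder's MLP
backbone trades representational capacity for CPU determinism — on real
dermoscopic texture a convolutional backbone at the full-scale profile
would be expected to separate subtler outliers. The min-max normalized
score is relative within a patient: it flags the most atypical lesions of
that patient and is not calibrated to malignancy probability.
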