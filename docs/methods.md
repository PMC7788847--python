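# Methods

This note records the models, conventions, and design decisions behind
`calciquant`, and what the synthetic validation does and does not show.

## The measurement problem

On bone-window CT finger images, healthy phalanges and calcinosis cutis
(CC) deposits are both calcium hydroxyapatite and therefore share an
intensity range. Lesion quantification consequently has to proceed by
*shape*: segment the phalanges, remove them, and measure what bright tissue
remains. The package implements that pipeline plus the statistics used to
compare an automated area estimate against a human one.

## Synthetic phantoms

`PhantomSpec`/`generate_phantom` produce a single-channel pseudo-HU raster
(default 64×64 px at 0.25 mm/px, i.e. a 16×16 mm field of view) containing:

- **Phalanges**: `n_phalanges` (default 3) capsule-shaped segments laid
  end-to-end along the vertical axis with small gaps as joint spaces,
  proximal segments longer and wider than distal ones, with random tilt,
  width, and position jitter. Default intensity 1200.
- **Lesions**: 0–3 star-convex polygons (7–12 vertices, radius jittered by
  `lesion_irregularity`) rasterised to pixels, giving pixel-exact
  ground-truth areas. Default intensity 1150 — deliberately overlapping the
  bone intensity so that intensity thresholding alone cannot separate
  lesion from bone and segmentation is genuinely required.
- **Noise**: additive Gaussian (sd 30) applied last and rounded to integer
  pseudo-HU; ground-truth masks are noise-free.

Lesion placement enforces two geometric constraints simultaneously: every
lesion pixel lies at Euclidean distance ≥ 2.0 px from bone, and at least
one lesion pixel lies at exactly that distance. The first guarantees that
the default 1-px bone-exclusion margin used during subtraction (a 3×3
dilation reaches at most √2 px) can never erode true lesion pixels; the
second keeps lesions adjacent to bone, as dystrophic calcifications
typically are. Placement retries up to a bounded number of attempts and
raises `PlacementError` if the geometry cannot be satisfied.

`truncate_phalanges=True` shifts the finger so a phalange is clipped by the
image border, emulating acquisitions in which the phalanges are
incompletely visualised.

**What the phantoms do not emulate**: dual-energy physics, partial-volume
edge blur, anatomical texture, soft-tissue structures, or between-patient
variability. Lesion edges are hard (a pixel is either lesion or
background), so pixel-exact area recovery on phantoms demonstrates
correctness of the measurement chain, not expected accuracy on clinical
images, where edge ambiguity would dominate.

Rotation augmentation defaults to the quarter-turns 90°/180°/270° applied
jointly to image and mask. Quarter-turns are lossless on the pixel grid, so
the count law (`n × (1 + n_rotations)` outputs) and mask disjointness
survive augmentation bit-exactly; arbitrary angles are available with
bilinear image and nearest-neighbour mask resampling.

Window/level display mapping (`apply_window`) is the standard linear ramp:
intensities at or below `level − window/2` map to 0, at or above
`level + window/2` to 1. The bone-optimised setting for these images is
window 1500, level 450.

## Bone segmentation

`UNetSegmenter` is a small encoder–decoder with skip connections — repeated
(3×3 conv + ReLU)×2 blocks, 2×2 max-pooling, nearest-neighbour upsampling,
and a 1×1 sigmoid head — implemented directly in numpy with explicit
backpropagation and Adam. Defaults (depth 3, 8 base channels, ~113k
parameters; loss = cross-entropy + soft Dice; lr 1e-3; batch 8; 30 epochs;
15% validation split) were chosen so training on 120 augmented 64×64
phantoms takes about two minutes on one CPU core while reaching held-out
Dice ≈ 0.99. Inputs are z-scored with statistics learned at fit time and
reflect-padded to a multiple of 2^depth. Training is bit-reproducible for a
fixed seed: all randomness (init, splits, shuffling) flows from one
`numpy` generator.

The epoch count is selected by `epoch_sweep`: train once per grid point and
recommend the smallest epoch count whose validation Dice is within 0.005 of
the sweep maximum. This replaces subjective visual comparison of successive
runs with an automatable plateau rule; ties resolve to the cheapest
adequate model.

`ThresholdBoneSegmenter` (global threshold → 8-connected components → drop
components below `min_region_px` → fill holes) is the classical baseline.
On noise-free phantoms whose lesion intensity is set below the threshold it
reproduces the ground-truth bone mask exactly, which anchors the learned
segmenter's evaluation harness with an independent oracle.

**Visibility gating** (`check_visibility`): an image is processable only if
the bone mask has at least the expected number of 8-connected components
(3 phalanges) and none touches the 1-px border margin. Failing images are
excluded from quantification and counted, mirroring clinical practice of
reporting "k of n images not amenable".

## Lesion quantification

`subtract_bone` masks the bone (dilated by `bone_dilation_px`, default 1)
to the image's background floor. Mask exclusion rather than intensity
arithmetic was chosen because it is idempotent and leaves non-bone pixels
untouched; the dilation margin prevents the bright rim at the bone boundary
from seeding false lesions.

`region_grow` formulation: seed candidates are local intensity maxima
(plateaus included) at or above `intensity_threshold`, using the
neighbourhood of the configured connectivity so that every thresholded
component contains at least one seed; seeds are visited in descending
intensity. A region admits a neighbouring pixel iff its intensity is at or
above the threshold **and** within `tolerance` of the running region mean
(updated incrementally). Grown pixels are claimed globally, so output masks
are pairwise disjoint; regions smaller than `min_lesion_px` (default 3) are
discarded as noise specks. Output order is descending pixel count with
centroid (row, col) tie-break, making results deterministic. In the
`tolerance → ∞` limit the procedure reduces exactly to connected-component
labelling of the thresholded raster — the oracle identity the test suite
checks exhaustively on random rasters. Defaults (threshold 600, tolerance
150) sit midway between the phantom background (~50) and calcium (~1150–
1200) intensities, ≥ 5 noise standard deviations from both.

**Axes**: the long axis is the maximum Feret diameter over foreground pixel
*centers* (computed brute-force up to 2000 px, via the convex hull above
that — both exact); the short axis is the extent of the projection onto the
perpendicular of the long-axis direction, clamped to the long axis to guard
against ulp-level excess in symmetric shapes. Distances between pixel
centers (not pixel footprints) keep the definition unambiguous and
oracle-checkable; a zero short axis (collinear or single-pixel masks) is
flagged `degenerate` rather than floored. Ellipse area is
`(L/2)(S/2)π`; ellipsoid volume is `(π/6)·d₁d₂d₃`, with `π/6 ≈ 0.52`, the
conventional clinical factor.

## Agreement statistics

- **Spearman**: Pearson correlation of average ranks. p-value: exact
  permutation enumeration for n < 10, the t approximation
  `t = ρ√((n−2)/(1−ρ²))` for n ≥ 10 (matching the common implementations at
  study-scale n). Constant series raise `ConstantSeriesError` rather than
  returning NaN.
- **Lin's CCC**: population (1/n) moments, per the original estimator —
  stated explicitly because sample moments change the value at small n
  (e.g. the hand example (1,2,3) vs (2,3,4) gives 4/7 with population
  moments). The 95% CI is Fisher-z with Lin's asymptotic SE; a percentile
  bootstrap CI is available via `ci="bootstrap"`. The attenuation property
  |CCC| ≤ |r| holds by construction and is property-tested.
- **Bland–Altman**: differences `d = x − y` (first-listed method minus
  second; the direction is recorded in the result so the sign convention is
  never implicit), bias = mean(d), `sd_diff` with the n−1 denominator, and
  limits `bias ± 1.96·sd_diff` using the conventional 1.96 multiplier.

`validate` composes all three, flags significance at p ≤ α (default 0.05),
and emits plots plus a CSV of plot coordinates so results remain testable
without graphics.

## Study runner

`run_study` executes the full design: generate 40 phantoms, split 30/10,
augment the training set ×3 (120 inputs), train, segment and
visibility-gate the test images, quantify, and compare the two area
estimators the pipeline itself produces — region-growing pixel-count area
vs ellipse-estimate area per lesion — with the full agreement analysis.
(An end-to-end human-vs-machine comparison is impossible on synthetic data;
these two estimators are the methodologically distinct pair the pipeline
can honestly compare.) All stage seeds derive from one master seed; the
manifest records the config, stage counts, and SHA-256 checksums of every
artifact (the model checkpoint is hashed by parameter content, since zip
containers embed timestamps), so a run is reproducible and tampering
detectable. A default run completes in ~3 minutes on one CPU core.

## Problem sizes used in validation

Tests and the acceptance script use: 64×64 phantoms at 0.25 mm/px; 30+10
train/test split with ×3 augmentation (120 training inputs); 30 training
epochs for the full model and 4-epoch/depth-2 models for fast pipeline
tests; 50 phantoms for area recovery; 1000 random 32×32 rasters for the
region-growing oracle; ≥ 200 masks for the axis oracle; 200 replicates at
n = 31 with σ = 3 mm² noise on areas uniform in 0.5–48 mm² for the
high-concordance simulation. The σ = 3 mm² noise level corresponds to
inter-rater variability a bit below the spread implied by typical published
limits of agreement for this measurement, i.e. a high-concordance regime.

## Known limitations

- Phantom realism is intentionally minimal (see above); clinical
  performance claims require real images.
- The segmentation network is desk-scale; no pretrained weights, transfer
  learning, GPU path, or 3D (volumetric/density) quantification.
- Region growing assumes bright lesions on a darker background with a
  roughly stationary lesion intensity; strongly graded lesions would need a
  locally adaptive admission rule.
- Bland–Altman here is the plain two-method form; repeated-measures and
  replicate-aware extensions are out of scope.
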