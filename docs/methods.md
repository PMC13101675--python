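# Methods

This note documents the models, conventions and numerical choices behind
`torporpose`, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

A recording pairs a `PoseTrack` — per-frame (x, y) image-convention
coordinates (y increases downward) of seven body parts at a fixed frame rate
— with a `TbSeries` of core body temperature sampled every 300 s. Video and
logger are assumed to start at the same session time t = 0; no drift
correction is applied. Pixel coordinates become millimetres by scaling with
the physical / on-screen cage width (`scale_to_mm`), which also corrects
small camera-height differences between sessions.

Keypoint samples whose estimation confidence falls below a cutoff (default
0.6) are replaced by linear interpolation between the flanking confident
frames; edge gaps take the nearest confident value. This is the simplest
rule that preserves trajectory continuity, and the interpolated fraction is
recorded on the track so users can audit it.

## Posture metrics

Body length (nose–tail base) and body width (hip–hip) are Euclidean
distances in the track's units. Angles are computed at a vertex keypoint as
the arc cosine of the dot product of unit vectors to two flanking keypoints,
in degrees; the head angle uses (right ear, **nose**, left ear), the
body-bend angle (nose, **back**, tail base). The arccos argument is clamped
to [−1, 1] to absorb floating-point overshoot; coincident points raise a
"degenerate angle" error rather than returning NaN.

Locomotion is the per-frame displacement of the back point, with frame 0
defined as 0. Binning uses fixed, contiguous windows; the arithmetic mean is
taken per bin and a trailing partial bin is dropped (and logged), so a 24-h
recording yields exactly 288 five-minute bins. Min–max normalization to
[0, 1] is performed per animal over the whole recording; a constant series
normalizes to zeros with a warning.

## Activity segmentation

**5-min scale.** Normalized binned locomotion is typically bimodal (mobile
vs immobile). A Gaussian KDE with Scott's-rule bandwidth is evaluated on
1,000 grid points; the grid is padded by three bandwidths past the data
range so the evaluated density carries essentially all probability mass.
The low-activity mode is the leftmost local maximum; the threshold is the
first inflection point to its right, found as the first sign change of the
discrete second difference of the density. Thresholds are fitted
independently per animal. Inputs with fewer than 20 bins, constant values,
or no inflection raise informative errors.

**10-s scale.** A bin is immobile when the cumulative back displacement
within it is strictly below 50 px. At every cutoff in the package, ties sit
on the mobile side (immobility requires `<`).

**Bouts.** Maximal runs of same-state bins are extracted by run-length
encoding, keeping runs of at least `min_consecutive` bins — 4 (≥ 40 s) for
torpor/sleep posture analysis, 1 (≥ 10 s) for transient cold-exposure
immobility. Torpor bouts are immobile bouts (5-min scale) lasting ≥ 30 min
whose Tb, linearly interpolated to 10 s, drops below 34 °C. Entry and exit
Tb are read from the interpolated series at the bin boundaries entering and
leaving immobility. Peri-bout profiles span 20 min before onset to 20 min
after offset, resampled onto a common normalized [0, 1] grid of 101 points
(configurable), averaged within animal and then across animals; windows
reaching past the recording are clamped and flagged.

## Egocentric features

Each frame is flipped to a math-oriented frame (y up), translated so the
back is the origin, and rotated by the proper rotation carrying the nose
onto the positive y axis. The rotation never reflects, so a mirror-image
pose flips the sign of ear/hip x coordinates and remains distinguishable —
this is what keeps left- and right-lying apart downstream. The 11 remaining
informative coordinates (nose_y; ear, hip and tail-base x/y) plus the mean
frame-to-frame nose displacement form the 12-feature vector; the feature
order is frozen so classifier weights are referable by name.

Nose movement is computed on raw (unaligned) coordinates: during immobile
bouts global motion is negligible, and raw displacement directly reflects
local sniffing/scanning movements. A per-bin mean (rather than sum or
variance) is used so the feature is independent of bin length. Per-bin
features are frame-averaged coordinate-wise; per-bout features average the
bout's bins.

## Clustering

Bout-averaged features are z-scored across bouts (population SD; constant
features are an error), projected with PCA — component signs fixed so the
largest-magnitude loading entry is positive, making results deterministic —
and the two-dimensional PC1–PC2 scores are clustered with a full-covariance
4-component Gaussian mixture (EM, 10 seeded restarts, covariance
regularization 1e-6, k fixed to avoid over-segmentation). Cluster →
semantic-label annotation is user input, as in any workflow where clusters
are verified against video; `suggest_annotation` proposes labels from
cluster-mean geometry (lying: large shared lateral ear/hip offset;
forward-facing: highest nose movement; curled-up: the remainder) but never
overrides the user. Merging maps exactly two raw ids to "lying".

## Classification

One fold per animal (leave-one-animal-out) prevents within-animal leakage.
Within each training fold: the majority class is randomly undersampled
without replacement to the minority size (one seeded draw per fold);
features are standardized; PCA keeps the smallest component count reaching
≥ 90 % cumulative explained variance; an L2 logistic regression (C = 1.0,
lbfgs, tol 1e-6, max 1,000 iterations) is fitted. Held-out bouts are scored
through the fold's own transforms. Torpor is the positive class; a predicted
probability of exactly 0.5 classifies as torpor. The ROC curve sweeps the
unique predicted probabilities and AUROC is the trapezoidal area, which
equals the pairwise Mann–Whitney statistic under ties. The shuffled-label
control permutes labels within each training fold — re-drawing the
undersample each shuffle — re-runs the full fold pipeline, and records 100
fold-averaged held-out accuracies. PC-space coefficients are back-projected
to the standardized feature space through the fold's loading matrix;
absolute values averaged across folds give per-feature attributions.
Significance testing of accuracy against the shuffle distribution is left to
external tools; the raw distributions are returned.

## Synthetic-data generator

The generator targets the statistical structure the analysis assumes, not
rodent biomechanics. A recording is a sequence of mobile and immobile
segments (durations kept to multiples of 300 s so 5-min bins stay
homogeneous). Mobile segments move the back point along a
heading-persistent random walk (default 25 mm/s) folded into a
259 × 234 mm cage, with a rigid "active" pose rotated to the heading.
Immobile segments hold a posture archetype at a fixed place and orientation.

Archetype geometry: the curled-up archetype realizes body length 42.32 mm,
width 33.99 mm, head angle 117.75°, and the stretched (AMP-like) archetype
59.09 mm / 31.11 mm / 63.21°, the measured cohort means for torpid and
AMP-injected mice; lying archetypes add a shared lateral ear/hip/tail offset
(left is the exact mirror of right), and the forward-facing archetype is
long and narrow (62 × 24 mm, 55°) with strong nose movement.

Noise model, in decreasing persistence:

- animal level: per-keypoint offsets (SD 0.6 mm), a log-normal size factor
  (SD 3 %), and a nose-movement-rate factor (SD 5 %) fixed per animal;
- bout level: a fresh per-segment pose perturbation (SD 0.8 mm per
  coordinate) and a log-normal micro-movement intensity factor (SD 0.2) —
  mice do not re-adopt a posture identically;
- frame level: isotropic Gaussian jitter, SD 0.1 mm per keypoint, plus
  archetype-specific extra nose noise realizing the target mean
  frame-to-frame nose displacement.

The frame jitter default keeps immobile 10-s back displacement below the
50-px rule with probability ≥ 0.99 at the default 2 px/mm scale (mean ≈
42 px at 12 fps), while mobile segments exceed it essentially always — the
segmentation ground truth is valid by construction.

Condition contrasts: sleep curled-up bouts are slightly less tucked
(tail base ≈ 1 mm, with nose-movement rate 0.22 vs 0.05 mm/frame); cold
curled-up bouts carry the strongest nose movement (0.9 mm/frame, emulating
cold-induced feeding/scanning head movements). These contrasts are
deliberately small relative to between-archetype geometry, so torpor and
sleep curled bouts overlap in PC1–PC2 and separate only through
higher-order, low-variance dimensions — the regime the classifier is
designed for.

Tb follows a baseline (36.5 °C) minus, for each flagged torpor segment, a
product of two logistic sigmoids: a slow descent (τ = 20 min) toward a
31 °C nadir and a faster rewarming (τ = 8 min), anchored analytically so
that Tb equals 35.19 °C at immobility onset and 33.45 °C at offset;
measurement noise is 0.05 °C. AMP recordings use the same Tb excursion under
a stretched posture; sleep and cold recordings stay at baseline.

What the generator does **not** emulate: limb kinematics, temporally
autocorrelated tracking error, within-bout posture drift, thermoregulatory
dynamics beyond the sigmoid shape, or occlusion/identity errors of real
pose estimation. Passing tests therefore demonstrate that the pipeline
recovers structure *of the kind assumed*, at the study's sample sizes — not
that it is robust to every artifact of real video.

## Problem sizes and determinism

Tests and the acceptance script run cohorts at 2 fps with 6–24 h recordings
(the analysis is frame-rate-agnostic: every rule is defined in seconds and
pixels, and per-frame nose displacement is a rate per frame in both the
generator and the features). Default cohort sizes mirror the recording
design: torpor n = 5–11, sleep n = 6, cold n = 6, AMP n = 11. All
randomness — generator, undersampling, GMM restarts, shuffles — derives
from explicit integer seeds via spawned `SeedSequence`s; the same seed
reproduces a cohort bit-identically.

## Known limitations

- The inflection-point threshold assumes a bimodal locomotion density;
  recordings dominated by a single state raise an error instead of
  guessing.
- Cluster annotation is heuristic-assisted but ultimately manual, as
  cluster identity can only be verified against video.
- Nose movement conflates tracking jitter with true micro-movement; with
  real data its floor depends on pose-estimation quality.
- A single top-down camera cannot see vertical posture changes or tail
  movement; the 12 features describe the horizontal silhouette only.
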