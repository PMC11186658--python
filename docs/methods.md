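# Methods

## The search procedure

The policy search treats augmentation selection as a small reinforcement
learning problem embedded in the training loop. The action space is a set
of `N_b` *buckets*, each an ordered list of `N_op` transform
specifications drawn uniformly at initialization — transform names with
replacement from the ten supported operations, magnitudes as uniform bin
indices — and frozen for the rest of training. Per-application randomness
(translation axis and sign, rotation plane, noise draws, elastic
displacement fields) stays live; only names and magnitudes are frozen.

The controller is deliberately minimal: a tabular score per bucket,
updated by ±1 from the sign of the change in validation loss, with cyclic
advancement to the next bucket on a negative reward. There is no learning
rate, no discount, no epsilon-greedy exploration; exploration happens only
when the currently active bucket hurts. The previous-loss register is
initialized to 1000 so the first comparison always rewards +1, and is
updated to the observed loss after every validation (without that update
the comparison target would stay at 1000 and the reward would almost
never be negative). By default an exactly unchanged loss leaves the score
untouched; `increment_on_equal=True` selects the variant in which
equality also increments, which some descriptions of the rule imply. Ties
in the final Q-table resolve to the lowest bucket index.

### Assumptions and scale-dependence

The reward is informative only when validation losses plateau or
oscillate: early in training almost every validation improves on the
last, every reward is +1, and the controller never leaves its starting
bucket. In full-scale training (hundreds of epochs) most of the schedule
is past the initial descent, so the signal is meaningful. In this
package's desk-scale demos (tens of epochs, a linear model) the descent
often dominates, and the search can lock onto whatever bucket it started
with — the worked example in the README shows exactly this. The
`run_mock_search` harness isolates the controller from that confound by
simulating per-bucket improvement probabilities directly; there the
controller identifies the best of four buckets in ≥95/100 replicates
after 200 rounds (the acceptance script recomputes this rate).

## Transforms

Ten operations over a `VolumePatch` (a 3D image in [0, 1], an aligned
integer label grid, voxel spacing in mm). Magnitude ranges, discretized
into 15 evenly spaced bins including both endpoints (step `(max−min)/14`):

| transform           | min | max  | magnitude meaning                         |
|---------------------|-----|------|-------------------------------------------|
| identity            | —   | —    | no-op (bins are placeholder zeros)        |
| translation         | 0   | 10   | shift in voxels; axis and sign drawn per application |
| elastic deformation | 50  | 150  | displacement-field amplitude (see below)  |
| zooming             | 1   | 2    | isotropic scale about the center, center-cropped back |
| rotation            | 0   | 0.52 | radians (≈30°) about a random grid plane  |
| intensity           | 0.1 | 1    | multiplicative scale (darkens)            |
| contrast            | 1   | 5    | gamma exponent on [0, 1]                  |
| sharpening          | 10  | 30   | unsharp-mask amount = magnitude/10, blur σ = 1 |
| smoothing           | 0.1 | 2    | Gaussian blur σ in voxels                 |
| gaussian noise      | 0.1 | 0.3  | additive noise σ                          |

Spatial transforms warp image and label with the same geometric map —
linear interpolation for the image, nearest-neighbor for the label — so
the output label values are always a subset of the input's; out-of-field
voxels fill with 0 / background. Intensity-only transforms never touch
the label. All outputs clip the image to [0, 1]. Neutral magnitudes
(identity, zoom 1, rotation 0, translation 0) short-circuit to an exact
copy, so bit-exact neutrality does not depend on interpolation round-off.

Where a named operation admits several conventional definitions, one was
fixed and documented rather than left implicit: intensity is
multiplicative, contrast is a gamma curve, sharpening is unsharp masking
with a fixed σ=1 blur. Elastic deformation uses a single-knob
parameterization: per axis, i.i.d. uniform noise in [−1, 1] smoothed by a
fixed Gaussian of σ=8 voxels and scaled to `0.02 × magnitude` voxels of
peak amplitude (so the 50–150 range maps to roughly 1–3 voxels of
displacement). The smoothing σ and the 0.02 scale are module constants
(`ELASTIC_FIELD_SIGMA`, `ELASTIC_SCALE`) and can be overridden. Buckets
may contain duplicate transforms; the uniform draw is with replacement.

A `TransformSpec` can pin its per-application draws (e.g.
`params={"axis": 0, "sign": 1}` for translation), which makes saved
policies replay exactly and gives tests closed-form geometric oracles.

## Training harness

Preprocessing follows the standard CT pipeline: per-sample min–max
normalization of acquisition-unit intensities to [0, 1] (constant volumes
are an error), then zero-padding each axis to the next multiple of the
patch size and non-overlapping tiling into cubic patches (96³ is the
conventional full-scale ROI; the tests and demos use 16³ patches from 32³
volumes to keep everything CPU-fast). `unpatchify` inverts the tiling
bit-exactly.

The loss is the unweighted sum of soft-Dice (averaged over classes, with
an empty class against an empty prediction scoring 1) and voxel-mean
cross-entropy; inputs must be per-voxel normalized class probabilities.
Evaluation reports mean per-class Dice over volumes, classes taken from
the union of foreground ids in the truth.

One bucket is active per validation interval and augments every training
patch in that interval, with fresh per-application randomness each epoch;
validation and test sets are never augmented. The number of controller
updates is exactly `floor(epochs / K)`.

### Built-in test model

`GaussianFeatureSegmenter` is a voxelwise linear softmax over four
features — a bias, the raw intensity, and Gaussian-smoothed intensities
at σ = 1 and 2 — fit by gradient descent on cross-entropy with
inverse-class-frequency voxel weights (without the weighting the
background swamps the small organs). It is deterministic given its seed,
trains in milliseconds per patch on one CPU, and segments
intensity-separable structures such as the phantoms to Dice > 0.95 in
domain. It is a test fixture, not a segmentation network: it has no
spatial receptive field beyond its smoothing scales, and conclusions
about real CT require plugging a real model into the
`fit_step`/`validate`/`predict` contract. Sliding-window full-volume
inference is intentionally out of scope; evaluation runs per patch.

## Synthetic phantoms

`make_phantom` renders a background (base intensity 0.2), one or more
large ellipsoids (class 1, intensity 0.6, semi-axes ≈ 22–30% of each
dimension) and mirrored pairs of small ellipsoids (class 2, intensity
0.85, semi-axes ≈ 8–12%), then applies an additive intensity offset, a
gamma curve, additive Gaussian noise, and clips to [0, 1]. Labels are
generated before the appearance stage and are therefore exactly invariant
to every appearance parameter — domain shift is covariate shift by
construction. Geometry is jittered per volume; organs that cannot fit
raise an error.

What the generator emulates: cross-scanner shifts in brightness, contrast
and noise, organ-scale contrast between a large and a small structure,
and per-subject geometric variability. What it does not: CT physics (beam
hardening, HU calibration), anatomical context, texture, pathology, or
class overlap ambiguity. Passing tests therefore certify the algorithmic
machinery (transform algebra, controller arithmetic, training-loop
contracts), not clinical segmentation performance.

Defaults: 32³ volumes, spacing 1 mm isotropic, noise σ = 0.05 in the
source domain; the demo target shift is offset −0.08, gamma +0.4, noise
+0.05 — large enough that an unaugmented model visibly degrades, small
enough that the organs stay separable.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.Generator` seeded at entry
  points; identical seeds give byte-identical run artifacts (logs,
  Q-tables).
- Validation losses must be finite and non-negative; NaN or negative
  losses raise instead of silently corrupting the reward.
- `dice_score` of two empty masks is 1.0 (the conventional definition for
  absent structures).
- Magnitudes outside a transform's range raise at application time, which
  guards against corrupted bucket files.
- Zoom output-shape rounding is padded back before the center crop so the
  output shape always equals the input shape.

## Problem sizes used by the test suite and acceptance script

Tests run on 16³–32³ phantoms with the built-in model; the full suite
takes well under a minute on one CPU. The acceptance script uses 100 × 200
mock-search rounds and an 8-source / 4-target phantom study at 32³ with
16³ patches, 24 epochs, validation every 2 epochs, 6 buckets × 3
operations — a scale chosen so the whole study reruns in seconds while
still exercising every stage of the pipeline.

## Known limitations

- The search's benefit is scale-dependent (see above); at demo scale the
  bucket policy can underperform per-sample random augmentation.
- No world-coordinate resampling: volumes are used in index space, and
  spacing is carried as metadata only.
- No anisotropic per-axis magnitudes, no learned magnitude tuning, no
  deep or double Q-learning variants.
- The config file is a flat key=value format; nesting is out of scope.
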