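# Methods

This note documents the models and numerical choices behind `graspkin`: the
preprocessing and feature definitions, the discriminability statistics, the
decoding protocol, and — in most detail — the synthetic trajectory
generator, since every quantitative claim the test suite makes is made on
its output.

## Preprocessing

**Filtering.** All marker coordinates are low-pass filtered with a
2nd-order Butterworth applied forward and backward (zero phase), cutoff
6 Hz at a 100 Hz sampling rate.  The dual pass squares the magnitude
response, giving |H(f)| = 1/(1 + (f/f_c)⁴); a 30 Hz noise component
survives with amplitude < 0.2%.  The order is exposed in
`SegmentationParams.filter_order`.  Filtering precedes segmentation and all
feature computation; wrist speed is the norm of the central-difference
derivative of the filtered wrist track (one-sided at the trial ends).

**Segmentation.** Reach onset is the earliest sample whose speed exceeds
20 mm/s and stays above it for every sample in the following 100 ms window;
offset is the first sample below 20 mm/s *after the post-onset speed peak*.
The peak constraint is deliberate: transient sub-threshold dips before the
main transport must not terminate the reach.  If the speed never drops, the
last sample is used with a warning.  Re-running detection on the segmented
window reproduces its own bounds (an idempotence property in the tests).

**Epoch normalization.** Each per-sample feature series is evaluated at
onset + p·duration for p = 10%, …, 100% by linear interpolation between
neighbouring samples (nearest-sample selection available as an option).
Interpolating between two unit normals yields a vector slightly inside the
unit sphere, so finger-plane triplets are renormalized per epoch after
interpolation; the matrix invariant ‖n‖ = 1 then holds exactly.

**Outlier replacement** operates on the epoch-level feature matrix, after
extraction and before any statistics or classification, in two passes.
(1) Participant level: within each participant × object-size cell, values
more than 2 SD (unbiased) from the cell mean per feature and epoch are
masked and refilled by linear interpolation along the trial's epoch axis;
masked endpoints are extrapolated linearly from the two nearest unmasked
epochs.  This 1-D interpolation is the natural specialization of
PDE-based inpainting to a 10-point series.  A trial with all ten epochs
masked for a feature is flagged and set to the cell mean profile.
(2) Group level: values more than 2 SD from the pooled per-object mean are
replaced by a seeded uniform draw on the interval from the group mean to
one SD *on the outlier's side* — keeping replacements on the correct side
of the mean.  On default synthetic data each pass touches ~4% of cells.

## The hand frame and features

F_local is rebuilt at every sample (the hand rotates ~20° during
transport): origin at ind1, x̂ = unit(lit1 − ind1) pointing ulnarly,
ẑ = unit((rad − ind1) × (lit1 − ind1)) dorsal, ŷ = ẑ × x̂ distal.  The
cross-product order is chosen for a right hand; left-hand data can flip it
via the `handedness` argument.  Note the ulnar semantics fix the x-axis
direction as lit1 − ind1 (ind1 − lit1 would point radially).

The finger-plane normal (plane through thu0, ind3, thu4, expressed in
F_local) needs a sign convention.  We orient it by the thu0 → ind3 → thu4
triangle winding, with a continuity rule (maximal dot product with the
previous sample) within a trial.  A dorsal-positive rule (z ≥ 0 at the
first frame) was considered and rejected: the normal of a realistic grasp
posture is nearly orthogonal to the dorsal axis (z-component ~0.05–0.19,
between-participant spread of the same order), so a z-sign rule flips a
substantial fraction of trials and makes the finger-plane features
bimodal.  The winding is anatomically fixed — thumb and index cannot pass
through each other — and agrees with dorsal-positive in the canonical
posture.

Trials that fail segmentation (e.g. no movement) are dropped with a logged
reason; rigid motions of a whole trial leave all local-frame features and
the grip aperture unchanged to 1e-6 (tested), while wrist height tracks
vertical translation exactly.

## Discriminability

Single-feature F-scores use unbiased variances; both-variances-zero cases
return 0 (equal means) or +inf with a warning.  The F-group denominator is
the *sum* of covariance traces, the within-class scatter of the classic
Fisher criterion; a difference-of-traces variant is retained as
`as_printed` mode for audits but can be negative or vanish and is not the
default.  Before the group score, each feature is centered and scaled by
its pooled **within-class** SD, sqrt((σ₊² + σ₋²)/2) — the classic pooled
estimator.  Scaling by the overall SD instead would include the
between-class separation in the scale, capping each feature's standardized
separation at 4 and distorting the temporal profile of the group score for
strongly separated features; with within-class scaling the mixed units
(mm, mm/s, unitless) contribute comparably and the score remains a pure
scatter ratio.

Epoch-wise contrasts mirror the repeated-measures post hoc convention:
trials averaged within participant × size, paired t across participants
per feature and epoch, Bonferroni correction within each feature's
ten-epoch family (a global 120-test family is available via
`family="all"`).  Zero-variance paired differences fall back to an exact
two-sided sign test and are flagged.

## Decoding protocol

Per epoch, independently: stratified ten-fold CV (seeded, shuffled),
per-feature z-scaling fit on the training folds only, RBF-SVM with C and γ
selected by exhaustive grid search over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
γ ∈ {2⁻¹⁵, …, 2³} (libsvm-guide ranges).  Hyperparameters are scored by
the same CV whose mean accuracy is reported — standard practice, but a
selection-biased estimate; `nested=True` re-runs the search inside every
outer training split for an unbiased one.  Ties break toward the smallest
C, then the smallest γ, making the search deterministic.  If the smallest
class has fewer members than folds, the fold count is reduced with a
warning.

Because chance-level behaviour and directional accuracy patterns are
insensitive to grid resolution, the simulation-level checks and the
acceptance script use a scaled-down 2 × 2 grid (C ∈ {2⁻¹, 2³},
γ ∈ {2⁻⁷, 2⁻³}); with 20 replicate null datasets of 900 trials this keeps
the chance-level control to a few minutes on one CPU.  Note that on null
data the grid-searched accuracy is biased slightly *above* 50% (a max over
noisy estimates), by well under one percentage point at these sizes.

## Synthetic generator

The generator emulates a table-top grasping study: 15 participants × 60
trials (30 per object size), 100 Hz, ~480 mm transport, a ~1.5 cm "small"
vs ~5 cm "large" target.  Its class grand means (temporal average over the
ten epochs) default to the group means of the reference study — grip
aperture 42.17/73.82 mm, wrist velocity 521.25/555.74 mm/s, wrist height
68.76/85.08 mm, plus the digit local coordinates and finger-plane
components.  All size effects scale with `effect_scale`; at 0 both classes
are statistically identical.

**Movement model.** The wrist follows a minimum-jerk transport
y(τ) = A·(10u³ − 15u⁴ + 6u⁵) with a mild time warp
u = τ + κτ(1 − τ), κ = ±0.03·effect_scale, so the small-object speed
exceeds the large-object speed early and the reverse late, crossing near
mid-movement.  Wrist height adds a size-neutral arch (sin²πτ bump) plus a
size effect growing smoothly from zero — heights coincide early in the
reach and separate from mid-movement on.  Grip aperture is a smoothstep
open-then-close base profile (start 18 mm, peak ~65–70% of movement time,
contact at mean object diameter + 10 mm margin) plus a growing size
effect, 12% of which is already present at onset: hands pre-shape from
movement start and the difference keeps growing toward contact.  These
growth shapes reproduce the temporal structure the repeated-measures
contrasts of such studies report (aperture separating from the very
beginning, wrist height only from ~40%) and make the information about the
target accumulate monotonically over the reach.

**Hand geometry.** The hand frame markers sit at fixed local positions
(rad at (20, −80, 0) mm, lit1 at (55, 0, 0)), carried along the wrist path
with a 20° pronation released over the transport.  Thumb and index tips are
placed symmetrically about a digit midpoint along a separation direction
constrained orthogonal to the prescribed finger-plane normal, at distance
= aperture; thu0 is placed inside that plane.  The finger-plane normal
itself follows an arc on the unit sphere whose width is solved so the
epoch-averaged normal matches the configured (sub-unit-norm) mean, plus a
class tilt.  Digit-posture size effects grow linearly over movement time
(slope 1.8 about the mean epoch).  One consequence of the orthogonality
constraint: the printed digit means and finger-plane normals of the
reference study are not exactly mutually consistent, and the generator
favors the finger plane, leaving epoch-averaged digit x-coordinates ~4 mm
from their configured means.

**Closed-loop calibration.** Rather than trusting analytic approximations,
the per-class movement duration (targeting the wrist-velocity grand mean),
arch amplitude and height effect (wrist height), and aperture peak and
effect (grip aperture) are solved numerically — Brent's method for the
duration, one-step affine (secant) solves for the amplitudes — with each
candidate evaluated by simulating a noiseless trial and running the *actual*
extraction pipeline (filtering, segmentation, epoch interpolation).
Feature-mode generation draws directly from the same noiseless extracted
per-epoch profiles, so both modes share one source of truth; at low noise
their per-class grand means agree to well under 5%.  Residual calibration
error is dominated by sample-count quantization of the segmentation
(~±2 mm/s, ~±0.5 mm), far inside the simulated standard errors.  Models are
cached per configuration.

**Variability.** Between-participant SDs default to the reference standard
errors × √15; within-participant (trial) SDs default to the same magnitude,
since only group SEs are reported — an assumption, exposed in the config.
Participant and trial offsets shift each feature additively (wrist velocity
through the trial duration, T = T_class·v_class/v_trial, which realizes the
offset exactly and makes slow/fast trials longer/shorter); digit offsets
move index and thumb as a common hand-posture offset so they cannot leak
into the aperture; finger-plane offsets tilt the normal before
renormalization.  A per-epoch jitter of 0.3 × trial SD models
epoch-to-epoch measurement variability (without it, an outlying trial would
always have all ten epochs masked at once), and i.i.d. marker jitter of
0.3 mm emulates optical tracking noise.  Unrealizable draws (non-positive
speed or duration) are redrawn a bounded number of times, then fail loudly.

**What the generator does not model** — and what passing tests therefore do
not show about real data: finger joint chains and tendon constraints,
object contact and lift, gaze- or fatigue-dependent drift, marker dropout
and occlusion, left hands, and any within-trial correlation structure
beyond the smooth profiles plus the noise terms above.  Chance-level,
calibration and directional results validate the *pipeline*; they are not
evidence about any particular laboratory's recordings.

## Problem sizes and determinism

The test suite and the acceptance script use the default study size (900
trials) for calibration and chance-level checks (20 replicate seeds for the
latter), and smaller configurations (2–8 participants) for geometry and
protocol tests.  Every stochastic stage takes an explicit seed;
`run_full_analysis` spawns named substreams (generator, group-outlier
draws, CV folds) from one master seed, so a rerun with the same
configuration reproduces the report exactly.

## Known limitations

* The calibration loop assumes the default segmentation parameters; custom
  thresholds shift grand means by the (small) change in epoch placement.
* Grid-search accuracy is reported un-nested by default (selection bias of
  order one percentage point on null data at n = 900).
* The C3D container format is not read; motion-capture data enter through
  the documented TSV trial-table dialect.
* Only the two-class (small/large) design is implemented; the F-group score
  and the SVM protocol would generalize, the generator would not.
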