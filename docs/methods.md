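# Methods

This note records the model, the numerical choices, and the boundaries of
what the synthetic experiments establish.  It is written for someone who
wants to modify the package, not merely run it.

## Coordinate system and skeleton

Poses are 24 named landmarks with the navel first.  The body-relative frame
is defined by three operations applied per frame: translate the navel to the
origin; scale every upper-body landmark (nose, ears, eyes, shoulders,
elbows, wrists, thumbs, middle fingers) by 1/|navel→head-center|, where the
head center is the ear midpoint; scale every lower-body landmark (hips,
knees, ankles, toes) by 1/|navel→ankle|.  The ankle reference defaults to
the mean of the two ankle distances (`ankle_rule="mean"`); a single-side
rule is available because the definition is stated for "the ankle joint"
without choosing one.  The upper/lower split assigns the hips to the lower
group — the two reference segments naturally partition the skeleton at the
navel.  Normalization is idempotent and, because each joint's defining
vectors live entirely on one side of the split (or pass through the origin),
it leaves all eight reported joint angles unchanged.

Two normalization modes exist: per-frame (default; matches per-image
training targets) and per-sequence (scale factors frozen from the first
frame), since nothing in the output contract fixes the choice.

## Joint angles

Every joint angle is the angle between two limb vectors meeting at the
joint: knee = (knee→hip, knee→ankle), hip = (hip→navel, hip→knee), ankle =
(ankle→knee, ankle→toe).  The neck (neck→head-center vs neck→navel) and
lumbar (navel→neck vs navel→hip-midpoint) definitions are this package's
own convention — flagged here because no canonical definition exists for
them in this representation.  The default reporting convention is flexion,
180° minus the vector angle, so a straight limb reads 0° and gait knee
flexion spans roughly 0–40°; the raw vector convention is exposed.

Angles use `atan2(|u×v|, u·v)` rather than `arccos` of the normalized dot
product: near 0° and 180° the arccos form loses about seven digits, and the
package promises 1e-9-degree agreement with closed-form oracles.

## Synthetic data generator

The generator emulates a capture studio for articulated characters:

- **Characters** are parametric stick figures; each of the 13 template
  segment lengths (rough adult proportions, meters) is drawn uniformly
  within ±8% of the template, deterministically from the seed.  Ninety
  seeds give ninety distinct bodies.
- **Circle walk** (default: 1 m diameter, two laps, 1.8 steps/s): the navel
  follows the circle at constant angular speed with the heading tangent to
  it; hip/knee/ankle/arm angles follow sinusoids at half the cadence (one
  gait cycle = two steps), the right side phase-shifted by π.  Knee flexion
  uses a raised-cosine so it stays in [0, amplitude], default 0–40°.  A
  1.5 cm vertical bob at twice the cycle rate adds realism.
- **Rotation in place**: fixed navel, constant yaw rate (36°/s default),
  arms abducted 90° — the protocol used for cross-validating against an
  optical reference, because per-axis correlations survive the two systems'
  different coordinate conventions while gait does not.
- **Dance**: every joint channel is white noise low-pass filtered at the
  smoothness cutoff (1.5 Hz default, zero-phase), scaled to per-joint
  limits; knee channels are folded to nonnegative.  Used for training
  diversity and as the package's source of "arbitrary valid poses" in tests.

The renderer is a pinhole camera 3 m from the navel with the body center on
the optical axis (the camera tracks the subject), focal length 1.1 × the
image side, drawing bones as anti-aliased thick segments on a plain or
noise background.  What it does **not** emulate: clothing, occlusion,
lighting, lens distortion, background clutter, camera shake, other people.
A green learning test therefore establishes that the representation,
codec, optimizer and decoding rules work — not that the network generalizes
to video of humans.

## Pose codec

The encoding cube is centered on the navel with half side 1.5: normalized
reference lengths are 1, so limbs fit with margin.  Cell (0,0,0) is at the
(−,−,−) corner; cell centers are at −h + (i+0.5)·Δ with Δ = 2h/G.  Points
exactly on a + face belong to the last cell.  Offsets are the displacement
from the cell center divided by Δ/2, so they span [−1, 1] and a
tanh-activated head can express any in-cell position; decode reads the
offset only at the chosen cell.

Ties in the hottest-cell search break to the smallest x-fastest linear
index (l = i + G·j + G²·k) — deterministic and testable.  Temporal matching
considers cells within 20% of the maximum normalized heat and scores each
candidate by log(heat) − d²/2σ², where d is the distance to 2·p₁ − p₂ (the
linear extrapolation of the two previous decoded frames; p₁ with one frame
of history) and σ = 0.5 body units is the expected per-frame motion scale.
Blending evidence with continuity matters: a pure nearest-to-extrapolation
rule locks onto wrong tracks once the band is wide enough to contain the
true cell, and a 5% band almost never contains it when the network is
genuinely ambiguous.  With no history the hottest cell wins and ties fall
back to the linear index.  Confidences are the maximum of the sum-normalized heat: 1 for a
one-hot grid, 1/G³ for a uniform one.  Training targets are one-hot by
default; a Gaussian mode exists because smoothed targets are common in this
family of methods and the right choice is not settled.

## Network and training

The network is a residual CNN over the channel-concatenation of three
consecutive frames (9 input channels).  The G³ output volume per keypoint is
realized as G depth slices of a G×G spatial map, keeping the backbone 2-D:
head channels encode (keypoint, output group, depth slice).  The desk
(`tiny`) preset is stem 5×5/4 → 3×3/2 → two 64-channel residual blocks with
a global-context layer between them → a 1×1 head, 112 px input, G = 14,
~260k parameters; `resnet34_like` mirrors the full-scale 34-layer
arrangement (stem + 3/4/6/3 blocks, 448 px, G = 28) and is provided for
structure, not for CPU training.  The global-context layer (mean-pool →
two dense layers → broadcast add) exists because extremity cells' receptive
fields miss the trunk, yet resolving which-leg-is-which at leg crossings
needs the body's heading; a width of 64 was the smallest that stopped the
backbone underfitting the depth of the ankles on the overfit benchmark.
Convolutions are im2col matrix multiplies with hand-written backward
passes; a finite-difference check in the test suite guards every layer
type.

Three numerical choices matter and were each verified empirically on
overfit probes:

1. **Spatial alignment.** Head map columns follow the grid x axis; head map
   rows follow the grid y axis *flipped*, because image rows grow downward.
   A weight-shared convolutional head can place heat only where its local
   patch sees evidence, so the output grid must be spatially registered
   with the image; with the flip omitted, training stalls at the all-zero
   heat solution.
2. **Loss balance.** The training loss is the sum of L2 terms for the four
   output groups, with the heat term summed over the grid and averaged over
   keypoints and batch, and the offset terms evaluated at the occupied cell
   (the only cell decoding reads) and averaged the same way.  A per-cell
   mean on the heat grid scales the localization gradient down by G³ and
   the network never learns to localize.  The public `loss` function keeps
   plain per-element MSE semantics for volume comparison.
3. **Head initialization.** The head starts at 1% of He scale.  The targets
   are sparse; with full-scale initialization the large random output
   collapses within a few steps, and Adam's second-moment memory of those
   transient gradients throttles the slow memorization phase that follows.

Optimization is Adam.  The full-scale preset keeps learning rates in the
1e-5–1e-6 range conventional for that scale; the tiny preset needs a much
larger rate to converge in ~3000 steps on one CPU (rates were compared on
overfit probes when choosing the default).  Shuffling and initialization are seeded; training is
bit-reproducible for a fixed seed and thread configuration.  Inference
slides a 3-frame window (N frames → N−2 poses) and feeds the two previous
decoded poses to the temporal matcher.

A trained network's confidences are *not* comparable to 1: the softmax over
G³ cells of a raw-score grid trained toward one-hot targets peaks around
e/(G³−1+e) ≈ 1e-3.  The 0.7 reliability threshold is meaningful for
probability-shaped heat (e.g. the codec's own output); for the desk network
the confidence is a relative, not absolute, quality signal.

## Output stage

Smoothing is a zero-phase (forward–backward) 2nd-order Butterworth low-pass,
6 Hz default at 30 fps — the filter family/order/cutoff are not fixed by the
output contract, and 6 Hz is the standard choice for human-gait kinematics;
the effective magnitude response is the square of the single-pass response
and the warm-up length is 10 samples.  Decimation is integer-ratio only
(60 → 30 fps).  The CSV dialect is documented in `gaitpose.pipeline`:
171 columns, 9-significant-digit floats (round trip exact to ~5e-9
relative), missing keypoints as empty fields rather than zeros, and
byte-deterministic output.  Per-joint reliability is the minimum AI score
over the joint's defining keypoints compared against the 0.7 threshold;
the aggregation rule is this package's choice.

## Validation

Time alignment maximizes the normalized cross-correlation of a designated
scalar channel over integer lags within ±max_lag; the planted-lag tests
require exact recovery in the noise-free case and ±1 sample at SNR 10.  A
lag on the search boundary is returned but flagged.  No spatial registration
between tracker and reference is attempted — the coordinate systems are
fundamentally different (body-relative and split-scaled vs global) — so the
comparison table reports per-keypoint, per-axis means of both streams plus
Pearson r, and nothing else.  TRC files are parsed with a hand-rolled reader
(no installed package reads TRC); units are converted to meters.

## Known limitations

- Stance/swing segmentation and any floor-referenced quantity are out of
  scope: the representation has no ground information, by construction.
- The generator's gait is sinusoidal, not biomechanically fitted; amplitude
  and phase defaults are plausible, not measured.
- The desk-scale learning test is a memorization experiment on one
  character; it validates the machinery, not generalization.
- Monocular depth of the feet is the weakest link, as it is for the real
  systems this emulates: at leg-crossing phases of gait, the network
  occasionally places an ankle at its mirror-image depth, and a handful of
  such frames dominates a Pearson correlation on knee flexion.  Which side
  suffers is sensitive to the training trajectory; the knee-tracking test
  is therefore the strictest in the suite and the first to turn red when
  the training recipe is perturbed.
- Single-person scenes only; the decoder has no data association across
  people.
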