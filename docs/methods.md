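# Methods

## The recognition problem

`kinaction` recognises human actions from 3D skeleton time series
(frames × 20 joints × xyz, Kinect-v1-style), in two regimes: *segmented*
(each test sequence is one action with known boundaries) and
*unsegmented* (an unbounded stream in which neither boundaries nor each
frame's position within its action are known). The method is built
around three ideas: a per-frame descriptor that is invariant to body
size and world position, a variance-based detector for the true start
of an action inside an irregularly segmented recording, and
confidence-weighted K-nearest-neighbour voting anchored at an estimated
per-frame time label.

## The angular spatio-temporal descriptor

For a smoothed sequence P(t) and a selected joint subset (default: head
and the full limbs, 13 joints — torso joints barely move relative to the
hip and mostly add dimensions), each frame t gets

    X_t = [ pose, λ·ω, ε·α ],            len(X_t) = 9 · m_sel

with, per selected joint i,

    pose_i = (η / L) · (p_i − p_hip)                       (hip-centred, hip-segment-normalised)
    ω_i    = (P_i(t+1) − P_i(t−1)) / d_i                   ("angular" velocity)
    α_i    = (P_i(t+2) + P_i(t−2) − 2·P_i(t)) / d_i        ("angular" acceleration)

where d_i is the length of the bone joining joint i to its parent and L
the hip-segment (hip-centre→spine) length. The differences come from a
5-frame window centred on t, so only four frames of latency separate a
frame from its descriptor. "Angular" is meant in the kinematic-chain
sense: dividing a joint's linear velocity by its bone length yields the
rotation rate of that bone, without any explicit Euler/quaternion joint
parameterisation.

**Why it is invariant.** Hip-centring and time-differencing remove
global translation; dividing the pose block by L and the derivative
blocks by d_i removes the subject's scale, because d_i and L are
measured from the subject being processed: each is the median over the
sequence's frames of the corresponding inter-joint distance. This
per-sequence estimation is deliberate — it is what makes a small and a
large performer of the same action map to the same descriptor (verified
to 1e−9 relative in the tests) — and it uses no labels, so applying it
on the test side leaks nothing into the model.

**Parameters.** λ = 0.8 and ε = 0.6 (dimensionless weights of the
derivative blocks against the pose block) are the defaults and are not
re-tuned per dataset here; η = 1.0 is redundant with the KNN metric
scale and kept only for completeness. Frame-period division is *not*
applied: ω and α are per-frame differences, so corpora at different
frame rates must be resampled before mixing — a configuration concern,
not a descriptor one.

**Edges.** The first and last two frames of a sequence have no complete
stencil. Default policy drops them (no fabricated kinematics); a
``copy`` policy duplicating the nearest interior derivative is available
and flags those frames.

**Smoothing.** Coordinates are pre-smoothed with a 5-tap sampled
Gaussian, σ = 1, along time. Boundary frames use the truncated kernel
renormalised to sum 1, so constants and affine ramps are preserved and
no frames are lost. Interpreted causally the centred filter delays the
signal by 2 frames; the delay is recorded in sequence metadata and
matters only when onset indices must be reported in raw-frame
coordinates.

## Finding the true action start

Public corpora often open with a frozen posture; the first recorded
frame is not the first action frame. The motion statistic

    S_d(t) = mean over monitored joints of Var( P_{i,d}(t−2..t+2) ),   d ∈ {x, y, z}

is the per-dimension population variance over the 5-frame window,
averaged over the monitored joints (default: the descriptor subset).
During stillness S is on the order of the squared sensor noise
(~4·10⁻⁶ for jitter sd 0.002); during motion it is orders of magnitude
larger. The onset T_start is the first frame where *every* dimension
exceeds Th = 0.005 (squared coordinate units) — the conservative
all-dimensions reading avoids firing on one-axis drift. The first two
frames carry copied, not measured, statistics and cannot witness a
crossing. Frames before T_start are dropped and time labels re-based so
T_start ↦ 0; training sequences in which no onset is found are excluded
with a warning. A √S variant (``onset_rms``) exists for thresholds in
coordinate units.

Th sits in a broad valley: the noise floor is ~3 orders of magnitude
below and action peaks sit ≥10× above, so accuracy is flat across the
recommended band 0.004–0.007 (the `sweep` verb reproduces this). Since
S scales with the square of the coordinate scale, Th is in squared
coordinate units and must be revisited if coordinates are not in
metre-like units.

## Training confidence

Early action frames (and any segment shared between classes — many
recordings share a "starting style") are poor witnesses for their class.
Every training frame X_t with true class A therefore receives

    c(X_t) = w(A) · K_t / K,      w(A) = N_total / (C · N_A)

where K_t of its K = 5 nearest neighbours among frames of *other*
training sequences share class A. Excluding the whole source sequence
(not just the frame) prevents trivial self-matches between adjacent,
near-duplicate frames. w(A) is standard inverse-frequency balancing so
long or over-represented classes do not dominate; on balanced corpora
w(A) = 1 and c ∈ [0, 1]. Class-ambiguous frames get small c and
correspondingly little say in classification.

## Recognition

Each incoming frame is processed independently (no assumption that
frame n+1 follows frame n — in a stream it may belong to a different
action):

1. **Time-label estimate.** The K = 5 nearest training frames (whole
   index, Euclidean metric) vote for their re-based time labels, binned
   with width b = 1; T_i is the winning bin's centre, ties to the
   smaller label. All-sample voting would degenerate to the global label
   prior, hence K-nearest voting.
2. **Windowed class vote.** The K nearest training frames whose labels
   lie within ±w_t (default 5) of T_i each vote with weight c(X); the
   window widens symmetrically if fewer than K qualify. This injects the
   global temporal ordering the local descriptor lacks: a mid-action
   frame is only compared against mid-action training frames.
3. **Accumulation.** A per-class tally sums vote weights over frames.
   Segmented: the argmax class after the last frame, scores normalised
   to sum 1. Streaming: once more than T_th = 15 frames are tallied and
   the leading class holds more than α_dec = 0.5 of the accumulated
   weight, the class is emitted and the tally resets (full reset by
   default; exponential decay behind a flag).

All KNN queries are exact (vectorised distance + sort) with a
deterministic tie-break: distance, then sequence code, then time label.
Per-frame cost is linear in the index size; the benchmark index
(~1 600 descriptors × 117 dims) classifies a few hundred frames per
second per core without any index structure.

**Streams and idle gaps.** The same motion statistic doubles as an
activity gate: a stream frame is idle when no dimension of S clears Th
(stillness is ~1e−6; any real motion clears Th in at least one
dimension, so the gate uses the *max* over dimensions, unlike the
deliberately conservative onset detector). Idle frames cast no votes
and do not advance the T_th gate, and a run of 10 consecutive idle
frames resets the tally — otherwise decisions fire on idle-gap noise
and one action's votes leak into the next. Sensor-provided per-joint
confidences can optionally multiply each frame's vote weight (off by
default; the source corpora document no formula for it).

## The synthetic benchmark

The generator produces exactly the structure the method assumes, so
every stage is testable without downloads:

* a 20-joint kinematic tree (hip-centre root, spine/head chain, 4-joint
  arms, 3-joint legs, bone lengths in metres for a ~1.7 m figure);
* actions as sinusoidal joint-angle programs on that chain (integer
  cycles over a 45-frame performance, so trajectories are band-limited
  and return to rest), plus a two-harmonic whole-body sway so no
  dimension's velocity vanishes for long;
* five default classes, including a direction-reversed pair
  (`punch_forward` / `punch_recoil`) that traces the same spatial path
  with opposite velocities — separable only through the ω/α blocks;
* a class-shared "wind-up" program for the first ~10 action frames (the
  shared starting style between the true start and the point where
  classes diverge), which is what gives early frames genuinely mixed
  neighbourhoods and low confidence;
* subjects with global scale (±15%), per-bone length jitter (±5%),
  speed factor (0.9–1.1), and per-sequence execution jitter (amplitude
  sd 8%, phase sd 0.08 rad) so two repetitions are never bitwise-equal
  trajectories;
* isotropic Gaussian coordinate noise (sd 0.002), a 30-frame frozen
  idle prefix, optional within-sequence repetitions, and concatenation
  into unsegmented streams with per-frame ground truth.

Amplitudes are calibrated so the idle noise floor sits ≥100× below Th
while action-segment S peaks ≥10× above it; a *sustained* 10× margin in
every dimension simultaneously is not attainable for band-limited
motion, because each dimension's velocity crosses zero periodically and
S_d dips at those instants regardless of amplitude.

Everything is a pure function of (parameters, seed); per-sequence seeds
are a splitmix64-style mix of the master seed with the (class, subject,
repetition) identifiers, so a corpus is stable under generation
reordering.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: skeleton-tracking failure modes (occlusion
swaps, jumping joints, per-joint dropout), non-stationary noise,
actions whose speed profile varies *within* a performance, inter-person
interaction, and the long indefinite holds of daily-activity corpora.
Results on the benchmark demonstrate correctness of the machinery and
recovery of generator parameters, not field accuracy.

## Protocols, sizes, determinism

Evaluation is always cross-subject: performers never appear on both
sides. The default benchmark is 5 classes × 8 subjects × 2 sequences
(odd-numbered subjects train → 40/40 sequences, ~1 600 training
descriptors), sized so the full pipeline — generation, training,
segmented and stream evaluation, onset study — completes in seconds
while keeping per-class test counts meaningful. The leakage canary
re-trains after permuting test labels and requires a bit-identical
model digest (SHA-256 over all arrays and parameters).

Numerical choices: population (not sample) variance in S; windows
centred on the first frame's value so constant input gives exactly
zero; Euclidean metric everywhere by default; argmax ties resolved
toward the smaller label / lexicographically first class; all RNGs are
`numpy` `default_rng` with explicitly derived seeds.

## Known limitations

* Time labels grow monotonically through within-sequence repetitions
  (re-basing trims only the onset); automatic episode splitting and
  end-of-action detection are out of scope.
* Frame-rate differences between corpora are not compensated in ω/α.
* The stream decision rule reports no calibrated probability, only the
  winning vote fraction, and has no explicit "unknown action" class
  beyond the α_dec gate.
* MSR-style `.txt` parsing is configurable (rows per frame, block
  layout) because the dialect is undocumented; the defaults follow the
  most common 40-rows-per-frame world/screen convention.
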