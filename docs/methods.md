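# Methods

`quathar` is a study harness for per-sample human activity and posture
recognition from wearable inertial/magnetic sensing. It covers the full
chain: simulation of labeled 9-axis recordings for scripted protocols,
quaternion attitude estimation by gradient-descent sensor fusion,
per-sample feature construction, a random-subspace KNN ensemble, and
leave-one-subject-out (LOSO) evaluation with confusion-matrix metrics.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Sensor and frame model

All quaternions are scalar-first Hamilton quaternions storing the
body-to-Earth rotation; the Earth frame is NED (gravity along +z, so a
static, level accelerometer reads `[0, 0, g]` with g = 9.81 m/s²). Euler
angles are intrinsic ZYX (yaw–pitch–roll). The magnetic reference is a
fixed unit vector with a 60° dip angle, `[cos 60°, 0, sin 60°]`; any
fixed direction not parallel to gravity suffices to make yaw observable,
so no geomagnetic model is consulted.

The simulated accelerometer measures specific force
`R(q)ᵀ·g_n + a_lin + δ_a`, the gyroscope `ω + b_g + δ_g`, the
magnetometer `R(q)ᵀ·m_n + δ_m`, with each `δ` i.i.d. zero-mean white
Gaussian per axis and `b_g` a constant per-recording rate bias
(default 0.01 rad/s per axis).

## Synthetic activity data

No public dataset exists for the scripted protocols this package
analyses, so recordings are simulated. Each activity is a profile: a
base orientation of the worn sensor plus per-axis sinusoidal orientation
oscillation and sinusoidal body-frame linear acceleration. Angular
velocity is obtained *analytically* from the orientation trajectory
(`ω = 2·vec(q* ⊗ q̇)`, with the product rule applied across transition
and oscillation factors), so the gyroscope stream is exactly consistent
with the stored ground-truth path — the property that makes filter
tests meaningful. Segment changes are entered through a smoothstep
transition (0.5 s at natural time scale) that also ramps the oscillation
envelope, keeping the path continuous and ω finite.

Key default choices, fixed once:

* **Static postures** (standing, sitting, laying, leaning, wait) differ
  only in base orientation — standing 0°, sitting −50° pitch (slouched
  pelvic tilt), leaning +30° pitch, laying −85° roll — with zero
  orientation oscillation and ~0.05 m/s² residual sway. Per-axis
  accelerometer readings therefore separate them; gyroscope readings add
  essentially nothing.
* **Stairs** ascend at +18° and descend at −18° mean pitch with
  *identical* oscillation and acceleration parameters. Because the
  linear-acceleration sinusoids are symmetric about zero, the
  acceleration-norm distributions of the two stair classes coincide
  (mean difference < 0.1σ) while their attitudes separate by 36° —
  the structure that makes attitude features informative.
* **Dynamic accelerations** peak near 0.8 g (amplitudes 8/2/6 m/s²),
  matching lower-back gait magnitudes; the ±18° gravity-tilt component
  (±3 m/s²) is swamped by the gait cycle, which is what defeats raw
  per-sample features on stairs.
* **Oscillation phases** per axis are offset (0, π/2, π/4): pelvic
  list, flexion and rotation do not peak together, so a dynamic
  activity's orientation orbit never collapses onto its base point
  (otherwise every walking cycle would pass exactly through the
  standing posture in feature space).
* **Noise** defaults (σ_acc 1.5 m/s², σ_gyr 0.15 rad/s, σ_mag 0.02)
  model sensor noise *plus* cycle-to-cycle movement variability. With
  sensor-grade noise alone every activity is a nearly deterministic
  curve that a KNN memorizes across subjects, which no real recording
  permits.
* **Subjects** differ by seeded multiplicative jitter (±10%) on
  amplitudes/frequencies and additive jitter (±5° per Euler axis) on
  base orientations; stair ascent/descent dynamics share one jitter
  draw per subject (a subject climbs and descends with the same tempo),
  which also preserves the norm overlap under jitter.

The three scripted protocols (postures; walk/run/jump; stairs with
turn-and-wait separators) are implemented verbatim; a fourth short
protocol supplies the leaning class, which the three main scripts do not
contain. Non-target activities (jumping jacks, wait, turn, run, jump)
are marker segments: they delimit and separate the target segments and
are stripped before classification.

What this generator does *not* emulate: impact transients and jerk,
soft-tissue artifact, magnetic disturbances, within-segment
nonstationarity, or realistic stair step events (stair segments are
modeled by duration, ~8 s for 11 steps). Passing tests therefore show
that the pipeline recovers the *designed* class structure under LOSO
generalization — not that the same accuracies would hold on real
recordings.

## Attitude filter

The estimator is the gradient-descent MARG fusion scheme: one
explicit-Euler step of the kinematic equation `q̇ = ½ q ⊗ (0, ω)` per
50 Hz tick, corrected by the normalized gradient of the alignment
objective between measured and predicted field directions, scaled by a
single gain β (rad/s):

    q̂_{t+1} = normalize( q̂_t + (q̇_gyro − β·∇f/‖∇f‖)·dt ).

The Jacobian is computed analytically from ∂R/∂q; tests verify it
against both a central-difference gradient (< 1e−6) and an independent
transcription of the published element-wise update equations (machine
precision). Magnetic distortion compensation rotates the measured field
into the Earth frame and collapses its horizontal part onto
`(b_x, 0, b_z)` before forming the objective, so horizontal-field errors
cannot tilt the estimate. An optional integral term with gain ζ
(default 0) compensates gyro bias drift.

Parameters and behavior:

* **β = 0.1** (default): converges in seconds on static input and
  filters measurement noise well at 50 Hz.
* **Convergence is slew-limited.** The normalized correction rotates the
  estimate at most 2β rad/s (≈ 11.5°/s at β = 0.1), so an arbitrary
  initial estimate cannot settle within 10 s; near the antipodal
  attitude the objective gradient is almost parallel to q itself and
  progress stalls — a property of the published algorithm, not of this
  implementation. Two standard remedies are provided and used: the
  default initialization computes an algebraic TRIAD attitude from the
  first accelerometer/magnetometer sample (no transient at all), and an
  optional warmup schedule (`beta_init`, default 2.5 for the first
  second) absorbs large initial errors when starting from identity.
  Convergence claims in the tests are made from a 90° initial error
  with the warmup schedule.
* **Observability**: with the accelerometer alone, yaw is unconstrained;
  roll/pitch still converge (verified), which is why the magnetometer is
  required for full attitude.
* Gimbal lock: quaternion-to-Euler conversion at |pitch| = 90° fixes
  roll = 0 and folds the remaining freedom into yaw; outputs are always
  finite and reproduce the input rotation.

## Classifier

KNN is instance-based: all computation is deferred to prediction, which
assigns a query to the class with the largest conditional probability
`P(y=j|x) = (1/K)·Σ_{i∈A} 1[y_i = j]` over the K = 5 nearest training
rows under Euclidean distance (exhaustive scan). Features are fed in
physical units with no scaling — a deliberate scale-sensitivity the
package documents rather than hides: distances mix m/s² with rad/s for
raw features, and quaternion components are dimensionless.

The random-subspace ensemble trains L learners, each on `d_l` feature
indices drawn uniformly *with replacement* (duplicates kept) and a
bootstrap row sample, combined by majority vote. Defaults: L = 30,
`d_l = ⌈D/2⌉`, `n_l = N`. Tie-breaking is deterministic at every level:
equal distances resolve to the lower training index (stable sort);
equal probabilities to the nearest neighbor among the tied classes;
equal ensemble votes to the first learner's neighbor ordering, with a
lexicographic fallback. A serialized model replays predictions
bit-for-bit.

## Evaluation

The confusion matrix is indexed `[predicted, true]`. Per class,
predictive value = diagonal/row-sum (complement: false discovery rate)
and recall = diagonal/column-sum (complement: false negative rate);
overall accuracy = trace/total. Reported percentages round half-up to
one decimal; raw fractions are retained. LOSO holds each subject out
exactly once; the pooled matrix is the cellwise fold sum, so pooled
accuracy is the sample-weighted fold mean.

The documentation's three-posture worked example (74,728 samples) fixes
eight cells and three marginals; the two sitting/laying off-diagonal
cells not determined by those constraints are completed symmetrically,
with the sitting diagonal chosen to match the example's stated overall
accuracy. All derived metrics are computed, never stored.

## Canonical experiments and problem sizes

The desk-scale study conditions, chosen once: 8 subjects at 50 Hz with
all four protocols compressed by `time_scale = 0.1` (≈ 18 000 samples
per subject; transitions compress with the timeline), features taken at
row stride 4 after marker stripping, and the ensemble run with K = 5,
L = 30, 2000-row bootstraps. Under these conditions, with fixed seeds:

* raw 6-axis features recognize static postures near-perfectly but
  collapse on stairs (recalls in the single digits to low tens of
  percent), confusing them with walking;
* quaternion features lift both stair recalls far above the raw-feature
  values while conceding some standing/walking confusion (per-sample
  attitude cannot fully separate a walking orbit from a standing point);
* norm features (‖acc‖, ‖gyr‖) lose most class information and fall
  far below raw features overall;
* adding gyroscope axes to accelerometer axes changes static-posture
  accuracy by at most ~2 points — the gyro carries no posture signal.

These are directional claims about recovered structure. Absolute
accuracies on real eight-subject recordings are out of scope: no such
dataset ships with the package, and nothing here should be read as a
reproduction of real-data numbers.

## Reproducibility

Every stochastic stage draws from a named substream of a single root
seed (`SeedSequence` keyed by stage/subject/learner), so any recording,
model or report is replayable byte-for-byte from `(config, seed)`.
Recording and feature CSVs round-trip losslessly (17 significant
digits, round-trip float parsing).

## Known limitations

* Sinusoidal signal profiles are a deliberately minimal model of human
  movement; the classifier results quantify structure recovery, not
  field performance.
* Per-sample classification ignores temporal context entirely; no
  windowed or spectral features are provided (out of scope).
* The Euler feature set inherits the pitch-singularity pathology and
  the subspace draw at D = 3 often selects uninformative axis pairs;
  its mediocre accuracy is expected, not a defect.
* The filter's operation count and real-time properties are not
  benchmarked; timing columns in comparison tables are informational.
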