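# Methods

This note documents the models, numerical conventions and design decisions
behind `gaitnorm`, and what the synthetic validation does and does not show
about real motion-capture data.

## Coordinate systems and joint angles

All marker positions are metres in a lab frame with x to the subject's
right, y in the walking direction and z up.  A segment frame stores
per-sample origins and a 3×3 axis matrix whose columns are the segment's
x (right), y (anterior) and z (superior) axes; the matrix is the rotation
taking segment coordinates to lab coordinates.

**Foot frame.**  Origin at the midpoint of the heel marker and the
MT1–MT5 midpoint; y is the unit vector from the heel to the MT1–MT5
midpoint; z is the unit cross product of the heel→MT1 vector with y; x
completes the right-handed frame.  The cross-product order is mirrored on
the right foot so that z stays superior and x stays to the subject's right
on both sides.  This heel-based long axis (rather than a malleoli→metatarsal
axis) avoids an implausible ankle-angle offset.

**Pelvis/thigh/shank frames.**  A minimal three-landmark construction:
z from the distal to the proximal (origin) landmark, the third landmark
fixes the sagittal plane, y = ẑ × (origin→lateral), x = ŷ × ẑ.  On left-side
segments the plane landmark lies on the subject's left, so its direction is
negated to keep x pointing right.  Full anatomical frame recipes (e.g.
hip-joint-centre regressions) are deliberately out of scope; any three
rigid, non-collinear landmarks per segment suffice for a planar-gait
validation.

**Joint angles.**  For each joint the relative rotation is proximal-to-
distal, `R = R_proxᵀ R_dist`, decomposed as `R = Rx(α)·Ry(β)·Rz(γ)`
(Cardan x-y-z).  α is the sagittal angle.  Signs are mapped so hip flexion,
knee flexion and ankle dorsiflexion are positive (the raw knee α is negated:
knee flexion rotates the shank posteriorly).  Within ~1e-8 of gimbal lock
(|β| → 90°) γ is set to zero and α absorbs the free rotation; ordinary gait
never approaches this.

## Foot signals

The virtual foot marker is the midpoint of the metatarsal-head midpoint and
the malleolar midpoint — a point near the instep where a shoe-mounted IMU
would sit.  Linear acceleration is the second central difference of its
position, `a_i = (p_{i+1} − 2p_i + p_{i−1})·f²`; the first and last samples
of a trial are flagged invalid and cycles are only extracted from the trial
interior.  Foot orientation is converted to unit quaternions
(sign-continuous along the series), and angular velocity is
`ω_i = 2·vec(dq_i ⊗ q_i*)` with dq by central differences.  Only the norms
‖a‖ and ‖ω‖ are used downstream.  Norms are invariant under any fixed
rotation of the marker cloud (equivalently, of a sensor's mounting
orientation), which is the premise of the whole approach; the test suite
asserts this end to end at 1e-6.

## Preprocessing and gait cycles

Markers are low-pass filtered at 10 Hz and vertical GRF at 56 Hz with a
fourth-order zero-lag Butterworth filter, implemented as a forward–backward
second-order pass so the *combined* response is fourth order.  (Whether
"fourth order, zero lag" means per-pass or combined is ambiguous in common
usage; combined was chosen and is configurable in one place.)

Heel contacts are upward crossings of a 20 N threshold on vertical GRF with
a 0.2 s refractory period.  Each crossing is refined to the loading onset —
the first sample after the last sample at or below a small floor (0.05 N) —
because a plain 20 N crossing on a physiological loading ramp lags the true
contact by several milliseconds.  A gait cycle runs from one heel contact
to the next ipsilateral heel contact, mapped to the nearest marker-rate
sample; one cycle (the first fully interior one) is analyzed per trial,
matching the study layout of one row per trial.

Each per-cycle channel is linearly interpolated onto 200 points at phases
i/199.  A feature row concatenates [ipsilateral ‖a‖, ipsilateral ‖ω‖,
contralateral ‖a‖, contralateral ‖ω‖] (800 values); a target row
concatenates the ipsilateral hip, knee and ankle angle waveforms
(600 values).  The channel order is fixed but arbitrary — any fixed order
is information-equivalent.  Rows are sorted by (subject, trial) so matrices
never depend on processing order.

## Waveform codec

Waveform matrices are t×d (trials × data points).  Each column is
standardized by its training mean and SD (a flat column raises rather than
being silently rescaled — it indicates an upstream bug) and the codec
projects onto eigenvectors of the training correlation matrix.  Kaiser
retention keeps components with eigenvalue ≥ 1; since correlation-PCA
eigenvalues sum to d, each retained component explains at least an average
column's variance.  Loading signs are fixed (largest-magnitude entry
positive) so results are reproducible across linear-algebra backends.
Retained component counts are data-dependent outputs, not constants: the
printed counts of the original study (65 input, 17 output) are properties
of its database and are not reproduced synthetically.

## Estimator

Subjects are shuffled once and dealt round-robin into five groups, so group
sizes differ by at most one and all ten trials of a subject share a group —
the unit of generalization is the subject, never the trial.

Tuning holds the test group out entirely.  The four remaining groups rotate
as validation (four "datasets"); per dataset the codecs are refit on the
three training groups and one network is trained per grid condition.  The
selection criterion is the mean absolute error between actual and predicted
validation *output scores*, pooled over all score-matrix entries and
averaged over the four datasets; ties break by grid order.  The default
grid is 12 layer/node combinations ({1,2,3,4} layers × {40,80,120} nodes) ×
batch {128,256,512} × dropout {0.3,0.4,0.5} × learning rate
{0.01,0.001,0.0001} = 324 conditions, i.e. 1,296 training runs; the
combination (1 layer, 80 nodes, 512, 0.5, 0.001) reported optimal for this
protocol is a grid member.  The layer/node axis is not uniquely determined
by the protocol description; this factorization was chosen to give 12
combinations containing that optimum, and every axis is configurable.

The network is fully connected: input → [dense → Swish → dropout] × L →
linear output, trained with Adam on MSE over shuffled minibatches for a
fixed number of epochs (no early stopping), everything seeded.  Dropout is
inverted dropout after each hidden activation; the output layer is linear;
PC scores enter the network unrescaled (no further normalization is applied
anywhere in the protocol).  Adam's per-parameter step adaptation is what
makes raw, differently-scaled score inputs trainable.  The trainer is a
compact numpy implementation — the architecture is small enough (tens of
inputs/outputs, ≤ a few hundred nodes) that a deep-learning framework
would add nothing but a dependency.

The main model refits both codecs on the four non-test groups, trains with
the winning condition, and predicts test waveforms by encode → forward pass
(dropout off) → decode.  A row-index audit in the tests verifies that test
subjects influence neither codecs nor weights.

## Evaluation

Per trial and joint: RMSE over the 200 points; NRMSE = 100·RMSE / (max −
min) of the *actual* waveform (range normalization, following the
convention of prior gait-estimation work; SD normalization is available);
Pearson ρ over the 200 points.  Each is averaged over trials (per-trial ρ
then averaged, which is how values like 1.00 at two decimals arise).
Constant actual waveforms are excluded from NRMSE/ρ with a warning.  Six
scalar timings are compared by MAE ± SD across trials: hip flexion and
ankle dorsiflexion at heel contact (point 1 of the cycle), peak hip
extension, peak knee flexion, peak ankle dorsiflexion and peak ankle
plantar flexion.  Peaks are full-cycle extrema; restricting, e.g., peak
dorsiflexion to stance would require phase segmentation that the protocol
does not define.

## Synthetic gait generator

The generator emulates the *structure* of a 200-subject barefoot
straight-walking database: 10 trials per subject (ipsilateral side
alternating, five per leg), markers at 200 Hz, per-limb vertical GRF at
1,000 Hz, both limbs modelled with the contralateral limb phase-shifted by
exactly half a cycle.

**Kinematic chain.**  Planar sagittal chain per limb: the pelvis advances
at stride_length × cadence with identity orientation; thigh orientation =
hip angle, shank = thigh − knee angle, foot = shank + ankle angle, all
rotations about lab x.  Foot landmarks ride rigidly on the foot frame with
heel and metatarsal markers in the sole plane, so the marker-based foot
frame and the sagittal Cardan angles reproduce the generating angles to
machine precision — the generator is the oracle for the kinematics module
(agreement asserted at 0.5° RMS, observed ~1e-14).

**Angle model.**  Hip/knee/ankle cycle templates are truncated Fourier
series (six harmonics, coefficients hard-coded) resembling normative
sagittal curves; subject s scales each template by an amplitude factor
(SD = subject_effect_sd, default 0.15; the ankle uses 1.5× that coefficient
of variation, reflecting the larger relative spread of ankle excursion in
normative data) and adds a small constant offset (SD = 2.5° ×
subject_effect_sd).  Trial-level variability is white noise low-passed at
8 Hz and rescaled to noise_sd_angle (default 0.3°), added to each joint
independently; markers are generated *from the noisy angles*, so features
and targets remain kinematically consistent within a trial.

Offsets are deliberately subordinate to amplitude effects: a constant
offset at the hip rigidly rotates the entire limb, and because translation
contributes no acceleration, rotation-invariant norm features carry *no*
information about it (knee and ankle offsets are only weakly visible
through chain geometry).  The dataset is built to exhibit a deterministic
feature→angle mapping up to the injected noise, so the unobservable
variance budget (offsets, trial noise) is kept small relative to the
observable amplitude variability.  This is also the honest physical reading
of the norm-based approach: absolute posture is partly invisible to it,
which is why hip accuracy trails knee/ankle accuracy on real data.

**Anthropometry.**  Segment lengths scale with a single stature factor
(SD 5%) and stride length follows stature and cadence with a roughly
constant walk ratio; cadence ~ N(0.9, 0.08) strides/s.  Correlated
anthropometry matches reality and keeps the nuisance manifold
low-dimensional.

**GRF.**  Per-limb vertical force is a two-peaked template
`1.15·W·(sin πs + 0.3·sin 3πs)` over stance (60% of the cycle by default),
exactly zero in swing; scheduled stance onsets double as the oracle for the
heel-contact detector (agreement within one GRF sample).

**Determinism.**  All draws derive from `SeedSequence` keyed by
(master_seed, subject index[, trial index]); identical configurations give
byte-identical datasets, independent of generation order.

**What the synthetic validation does not show.**  The generator has no
frontal/transverse motion, no soft-tissue artifact, no marker noise or
gaps, no double-support force sharing, shared body mass, and far smoother
inter-trial variability than real gait.  Passing the synthetic suites
demonstrates that the pipeline's machinery (geometry, events, codec,
tuning, leakage control, metrics) is correct and that the estimator
recovers a learnable mapping; it does not predict accuracy on real data.
Conversely, the headline accuracies of the original study (e.g. hip RMSE
7.0°) are properties of its database and are intentionally not targets of
the synthetic experiments.

## Problem sizes and numerical choices

The packaged experiments use 150 subjects × 10 trials for the scaled
tune/train/predict/evaluate runs (reduced 8-condition grid: {1,2}×80
nodes, batch 8, dropout {0, 0.2}, learning rate {1e-3, 3e-4}; 100 epochs)
and 200 subjects for the matrix-dimension bookkeeping — sizes chosen so a
full run completes in minutes on one CPU while leaving the learnability
margins wide.  Tolerances: frame orthonormality 1e-9; Cardan
compose–decompose 1e-9°; codec round trip 1e-8; metric-oracle agreement
1e-10; rigid-rotation invariance of features 1e-6 (filtering and event
detection amplify rounding slightly).  Degenerate inputs fail loudly:
collinear landmarks name the sample, flat waveform columns name the column,
non-finite training losses name the epoch.
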