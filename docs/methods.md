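# Methods

## The task and the measurement model

The package analyses sagittal-plane lower-limb pointing: a standing
participant points with the toe to a target and returns in one smooth
out-and-back motion, while hip, knee, ankle and toe markers are captured at
65 Hz.  The limb is modelled as a planar chain of three rigid segments
(thigh, shank, foot) joined by frictionless hinges, with the hip treated as
a fixed anchor within a trial.  Targets are participant-specific: the
flexed joints of a target combination are rotated to a fixed fraction
(default 0.6) of that joint's active range of motion, which normalizes task
difficulty across strength and flexibility levels.  Seven combinations are
presented (6 trials each per 42-trial block, one block per vision
condition); for analysis they collapse into three classes — HKA
(hip-knee ± ankle), KA (knee ± ankle), HA (hip ± ankle) — with the
ankle-only target labelled `uncollapsed` and excluded from three-class
analyses.

### Coordinate and sign conventions

x is anterior-positive, y upward-positive; segment angles are measured CCW
from the right horizontal and unwrapped, so upright stance is
(270°, 270°, 360°) for (thigh, shank, foot).  Joint angles are
flexion/dorsiflexion-positive with zero at neutral stance:
φ_hip = θ_thigh − 270, φ_knee = θ_thigh − θ_shank,
φ_ankle = θ_foot − θ_shank − 90.  Torques are flexor/dorsiflexor-positive
(knee flexion is a −CCW relative shank moment, hence the (+, −, +) sign map
from CCW chain torques).  These conventions are an implementation choice
made for internal consistency; they are not claimed to match any particular
motion-analysis software's native output.

## Torque decomposition

For each joint the applied joint torque is computed by a planar
Newton–Euler recursion over the distal chain (backward force/moment
propagation from the foot, hip linear-acceleration terms identically zero).
Writing the equations of motion of the chain distal to joint j as

    τ_j = Σ_s A_js(θ) α_s + Σ_s B_js(θ) ω_s² + G_j(θ),

every term is partitioned by its kinematic source:

* **gravitational torque** T_grav(j) = −G_j, the moment of gravity on the
  distal chain about the joint (computed geometrically);
* **interaction torque** T_int(j) = −Σ_{s≠d(j)} (A_js α_s + B_js ω_s²),
  the centripetal (ω²) and inertial (α) coupling terms sourced to segments
  *other than* the joint's own distal segment d(j), parsed per source
  segment and kind;
* **net torque** T_net(j): the remaining inertial terms, those driven by
  the motion of the joint's own distal segment;
* **muscle torque** T_mus(j) = T_net − T_grav − T_int, the residual.  It
  equals the physically applied joint torque and lumps active contraction
  with passive tissue moments.

Two identities hold at every sample by construction and are asserted across
the test suite to 1e−9 N m: net = muscle + gravity + interaction, and the
parsed interaction components sum to the interaction total.  An alternative
reading of the muscle-torque sign ("gravity + interaction minus net") is
available behind `literal_muscle_sign=True` for auditability; the default
orientation makes flexor muscle torque positive when flexing against
gravity, which is the only orientation consistent with the convention that
flexor torques and generative power are positive.

Muscle power is P(j) = T_mus(j) · φ̇_j with the flexion-positive joint
velocity, so Σ_j P(j) equals the total mechanical power delivered to the
chain; the suite checks that its time integral tracks the mechanical-energy
change within 0.5% on frictionless simulations.  The motor-strategy summary
statistic is the *signed* mean muscle torque over the first half of the
reversal phase (first toe-speed peak to the reversal point): a signed mean,
not a rectified one, because flexor and extensor strategies must remain
distinguishable.

### The independent cross-check

The synthetic module contains a second, deliberately independent dynamics
formulation used both to drive simulations and as an oracle: the mass
matrix is assembled from centre-of-mass Jacobians (M = Σ m J^T J + I), and
velocity/gravity terms come from complex-step derivatives of the kinetic
and potential energy.  Newton–Euler muscle torque and this energy-based
computed torque agree to ≤ 1e−6 N m on random smooth trajectories (observed
agreement is at machine precision, ~1e−13 N m); a symbolic Euler–Lagrange
derivation (sympy) provides a third route in one test.

## Kinematic processing

Markers are low-pass filtered with a 2nd-order Butterworth applied forward
and backward (zero phase, 4th-order effective attenuation) at 6 Hz; gaps up
to 3 samples are filled linearly, longer gaps are an error.  Segment angles
come from atan2 of distal-minus-proximal marker vectors, unwrapped and
shifted onto the neutral-stance branch; velocities and accelerations are
central differences (one-sided at the ends), filtered before
differentiation.  Trials are cropped to the moving portion (speed > 2% of
max, padded 5 samples).  The reversal phase spans the two largest local
toe-speed maxima (prominence ≥ 10% of the global max, ties to the earlier
index) and the reversal point is the speed minimum strictly between them;
fewer than two prominent peaks raises a detection error and the trial is
excluded and counted.  Movement time is the first-peak-to-reversal
duration.

End-point errors are the signed anterior (h) and upward (v) toe-target
differences at the reversal point, in cm.  Foot-path area integrates y dx
by the trapezoid rule over the outbound and return halves of the reversal
phase; the magnitude of the summed signed integrals is the enclosed area
(the difference between the two half-areas).  Terms are accumulated with
exact summation so a retraced path yields exactly zero.  The area is
log-transformed with a 1e−6 m² floor for the statistics stage.

## Proprioception scores

JPS is the mean absolute difference between the memorized target angle and
the reproduced angle over six trials per joint (deg; higher = poorer).  MDS
scores each non-catch trial as excursion-before-detection divided by the
10° maximum plus the direction response (0 correct / 1 incorrect), averaged
over the ten scored trials per joint; the score is bounded to [0, 2].  The
single catch trial is excluded from the score and reported as a validity
flag.  Per-participant summary values pool hip and knee of the pointing leg
by averaging — a labelled convention, since a single per-leg value requires
some pooling rule.

## Synthetic cohort

The generator stands in for motion-capture data and defines the study
conditions: 12 controls and 16 SCI participants; group-specific
anthropometrics (body mass 71 ± 13 kg vs 75 ± 15 kg, stature 1.70 ± 0.09 m
vs 1.69 ± 0.09 m, segments scaled by standard anthropometric fractions) and
active ROM (hip 64.7 ± 18.5° / 47.5 ± 10.0°, knee 103.1 ± 12.1° /
86.6 ± 17.8°, ankle 17.1 ± 6.3° / 10.5 ± 8.2°); markers at 65 Hz with 2 mm
i.i.d. Gaussian capture noise.

Each trial is planned as a minimum-jerk out-and-back joint trajectory
(0.3 s holds; out-phase duration ~ N(1.28 s, 0.46 s) clipped to
[0.6, 2.4] s, chosen so the *measured* movement time — about half the
out-phase for these speed profiles — reproduces the observed 0.64 ± 0.23 s).
The commanded torque is the energy-based inverse model of the plan with
three modifications:

1. **strategy distortion**: the feedforward command is multiplied by
   (1 + δ) at one joint per target class.  The four links — hip deficit at
   KA, knee excess at HKA, knee deficit at HA, ankle deficit at HKA — are
   linear in the participant's proprioceptive-noise parameter ρ, with the
   HKA knee link given a positive offset and negative ρ-slope so the SCI
   group shows a knee-flexor excess on average while worse movement sense
   predicts *less* knee flexor torque within the group.  Controls draw
   δ ~ N(0, 0.02).
2. **motor noise**: smooth (3 Hz low-passed) zero-mean torque noise with
   per-joint SD (0.40, 0.30, 0.015) N m per unit ρ, scaled to each joint's
   driven inertia.
3. **low-gain tracking**: a fixed joint-space PD term
   (Kp = 20/10/0.5 N m/rad, Kd = 4/2/0.1 N m s/rad) toward the planned
   trajectory, standing in for reflexive/impedance corrections.  A purely
   feedforward distorted command injects a sustained gravity-scale torque
   bias whose double integral diverges over a multi-second trial; the PD
   term bounds that drift while its gains are low enough that distortion-
   and noise-driven end-point errors of a few cm survive (a sustained
   1 N m hip bias, for instance, settles near 3° of thigh offset).  The
   recorded commanded torque is the total applied torque, so inverse
   dynamics on noiseless trials must recover it (observed: < 0.5% of peak
   unfiltered, < 1% filtered; asserted at < 1% / < 5%).

Forward integration is fixed-step RK4 with 16 substeps per output sample
(1040 Hz internally at 65 Hz output); any segment speed above 50 rad/s
aborts with a diagnostic.  ρ is drawn near 0.2 for controls; the 16 SCI
participants take ρ from a fixed severity spectrum spanning 0.13–2.43,
representative of movement-detection scores observed in motor-incomplete
SCI cohorts (note that spectrum's maximum exceeds the scoring formula's
bound of 2, so simulated scores saturate at 2).  JPS trials reproduce a 25° target with
Gaussian error of SD 6.6 + 8.5·ρ deg; MDS trials draw the pre-detection
excursion as 10·ρ·U(0.7, 1.3) deg capped at 10, with wrong-direction
probability clip(ρ − 1, 0.02, 1), so the expected session score tracks ρ
and an ideal observer (ρ = 0, zero floor) scores exactly 0 while a severe
deficit (ρ ≥ 1.43) saturates the excursion cap deterministically.  MDS
sessions are 5 flexion + 5 extension + 1 catch trial per joint per leg at
0.5/1/2 deg/s; speed is carried as metadata and does not enter the
simulated threshold.

Measured contrasts are *emergent*, not copied from the distortion
coefficients: the pipeline measures the torque of the realized movement,
so a feedforward excess that makes the limb overshoot is partly masked —
or even sign-inverted — by the deceleration the realized trajectory then
requires (with the default cohort this happens to the knee link at the HKA
target, where the measured group contrast comes out extensor-shifted
despite the flexor-excess command).  The hip-deficit link at KA and the
proprioception-severity associations do survive into the measured
quantities with their intended signs.

What the generator does *not* emulate: EMG/muscle-level dynamics, postural
sway and hip translation, vision-condition-dependent behaviour (vision is a
label only), marker soft-tissue artifacts, and trial-to-trial learning.
Passing tests therefore demonstrate that the measurement and statistics
chain recovers what this generative model injects — not that real SCI
pointing obeys this model.

## Statistics

All models are random-intercept linear mixed models (participant grouping)
estimated by maximum likelihood (statsmodels MixedLM).  The group model for
each outcome starts with group×target and group×vision interactions plus
maximum joint ROM and movement time as covariates (referents: HKA target,
full vision, control group); interactions with Wald p ≥ 0.05 are dropped,
and the three-way interaction is assessed only when both two-way terms are
significant (kept if significant and AIC-improving).  Wald statistics for
terms containing the between-participant group factor are referred to an
F distribution with between-within denominator df (participants − 2): the
asymptotic chi-square reference is measurably anticonservative at
a-few-dozen-participant cohort sizes (empirical type-I 0.045–0.075 vs
0.033–0.048 for the F reference in 400–600-replicate null simulations).
Default optimizer settings are used; the lbfgs path in statsmodels produced
invalid Hessians on a third of Monte-Carlo fits and is avoided.

Post-hoc SCI-minus-control contrasts per target marginalize over vision,
use t CIs with the same containment df, and apply a Šidák familywise
correction over the three targets (configurable to none).  Cohen's d
divides the contrast by the total SD √(σ²_participant + σ²_residual) by
default (residual SD optional).  Marginal R² is the fixed-effects variance
share var(Xβ)/(var(Xβ) + σ²_u + σ²_e), and Cohen's f² = R²/(1 − R²).
Crude associations are single-predictor random-intercept models (per-trial
torque vs performance; per-participant MDS/JPS vs torque).

The Monte-Carlo calibration of this stage (null type-I error within
[0.03, 0.07]; ~95% CI coverage of an injected group×target effect) runs on
a lightweight table-level generator that draws participant intercepts and
trial noise directly around cell means — the fitted model's own generative
structure — because forward-simulating hundreds of cohorts would add cost
without changing what the check verifies.  The acceptance suite uses 400
null and 200 coverage replicates with 28 participants × 24 trials.

## Numerical choices and limitations

* Angle arithmetic is done in radians internally; degrees at the API.
* Filter warm-up shorter than the padded length raises rather than
  returning garbage; sampling below twice the cutoff is rejected.
* The reversal detector requires two speed peaks with ≥ 10% prominence;
  degenerate (monotone or flat) profiles raise.
* Problem sizes in the analysis drivers (2 trials per combo per block
  rather than 6) are a deliberate reduced-cohort choice for the forward
  simulations; every estimator consumes the same table schema at any size.
* Joint-angle conventions and the hip/knee pooling rule for proprioception
  summaries are package conventions, stated above, not measured facts.
* The three-segment chain ignores pelvis motion and joint translations;
  muscle torque cannot separate uniarticular from biarticular sources.
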