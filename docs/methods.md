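# Methods

## Model

`gaitkf` estimates the pose of seven IMUs — pelvis, both thighs, shanks and
feet — treating each as an independent six-degree-of-freedom rigid body.
The nominal state per IMU is position, velocity and a Hamiltonian unit
quaternion (sensor→world); the filter operates on the 9·n error state
(δp, δv, δθ per IMU) in the error-state Kalman (ErKF) form: the nominal
state is propagated nonlinearly by strapdown integration, the error mean is
identically zero between updates, and only the error covariance P is
predicted, using the block-diagonal Jacobian of the strapdown step and
process noise σ_a²Δt², σ_ω²Δt² on the velocity and attitude blocks (zero on
position). The attitude error is a local (right-multiplicative)
perturbation, q ← q̂ ⊗ δq; all measurement Jacobians are derived under this
convention and verified against central finite differences of the
nonlinear maps.

One deliberate refinement: the position row of the strapdown step contains
½(Ra+g)Δt², so its exact linearization carries a −½R[a]ₓΔt² coupling from
attitude error into position error. The classical ErKF transition matrix
drops this term; we keep it so the analytic Jacobian matches finite
differences to full precision. At 128 Hz the term is ~3·10⁻⁴ relative and
has no practical effect on the estimates.

### Measurement corrections

All corrections observed at one time step are stacked into a single batch
update (one Kalman gain over the joint innovation); the innovation system
is solved by Cholesky factorization, never an explicit inverse, with a
10⁻¹² jitter fallback. After injection the error mean is reset and P is
mapped through the reset Jacobian G (attitude blocks I − [½δθ̂]ₓ). With no
events at a step, prediction passes through unchanged — with every
correction disabled the filter is bit-for-bit identical to raw strapdown
integration, which the tests assert.

* **ZUPT** (σ = 0.01 m/s): the foot IMU's velocity is zero at the single
  footfall instant detected per stance. The primary translational drift
  corrector.
* **Gravity tilt** (σ = 5.73°): a quasi-static IMU's accelerometer
  direction observes gravity. Suppressed when ‖a‖ leaves [0.8 g, 1.2 g].
* **Joint center** (σ = 0.01 m): adjacent segments must agree on the world
  location of their shared joint; applied at every step for all six
  joints. This couples the seven bodies into one chain and is what lets
  foot ZUPTs stabilize the whole system.
* **Joint axis, "soft hinge"** (knee σ = 1.15°, hip σ = 57.3°): the
  flexion axes of adjacent segments are biased — not forced — to stay
  aligned in the world frame. The tight knee value encodes near-hinge
  knee behavior; the two-orders-looser hip value merely keeps hip angles
  in realistic ranges while allowing full 3-DOF rotation. No axis
  correction is applied at the ankle.

Gyro-related defaults are stored in radians internally; configuration
files carry degrees (2.83 deg/s, 5.73 deg, 1.15 deg, 57.3 deg) and are
converted on load.

### Initial covariance

The initial error covariance is not dictated by the estimator itself; we
default to per-IMU diag(σ_p0², σ_v0², σ_θ0²) with σ_p0 = 0.01 m,
σ_v0 = 0.01 m/s, σ_θ0 = 1°, configurable in `NoiseConfig`. Results are
insensitive to this choice within an order of magnitude because the
per-step joint-center/axis corrections dominate after a few seconds.

## Event detection

Still periods are maximal runs with ‖ω‖ < 60 deg/s lasting at least
0.05 s, computed on the raw gyro norm (rotation-invariant, no smoothing).
Within each still interval of a foot IMU lasting ≥ 0.1 s, the footfall is
the sample minimizing the stillness energy ‖ω‖ + λ·|‖a‖ − g| (λ = 1 in SI
units, earliest index on ties). Two gates make the detector robust to the
fact that "rotating slower than 60 deg/s" is far from "still":

* an interval yields a footfall only if its best energy score is below
  0.3 (`max_footfall_score`) — mid-swing windows can rotate slowly while
  translating at 2 m/s and must not receive a ZUPT;
* tilt corrections are applied only at samples whose energy score is
  below 0.3 (`max_tilt_score`) — a slowly rotating but accelerating
  segment (pelvis sway, early/late stance) points its accelerometer up to
  tens of degrees away from gravity.

All thresholds live in `DetectionConfig`. A planted foot scores at the
gyro-noise level (~0.1 with the default noise), well inside both gates.

## Joint angles and stride metrics

Segment orientation is R_WA = R_WS·R_AS with R_AS the anatomical→sensor
rotation from calibration. Joint angles decompose R_proxᵀ·R_dist in the
body-fixed **Z-X-Y** sequence: flexion about the proximal medial-lateral
(z) axis, internal rotation about the distal longitudinal (y) axis,
adduction about the floating x axis. The recommended clinical conventions
do not pin down one literal matrix sequence, so this choice is isolated in
a single function (`joint_angles`) and an alternative sequence is a
one-line change. Left-side adduction and internal rotation are
sign-mirrored so positive means adduction/internal on both sides — a
convention, flagged as such. The ankle uses the same three-angle
machinery with DP/InEv/IE labels. Near gimbal lock (|cos β| < 10⁻⁶) the
decomposition returns NaN with a warning.

Angle series are low-passed with a zero-lag 4th-order Butterworth at 6 Hz
(forward-backward `filtfilt`); the design cutoff is pre-warped by
(√2−1)^(−1/8) so the *bidirectional* −3 dB point sits at the nominal
cutoff. NaN gaps split the series; segments shorter than 0.2 s are
dropped rather than filtered.

Per-stride range of motion is max − min between successive same-foot
footfalls; a stride containing any NaN is invalid, and a trial summary is
suppressed when more than 30 % of strides are invalid. Stride length is
the horizontal (world-xy) heel displacement between consecutive same-foot
footfalls; step width the perpendicular distance of the intermediate
opposite-foot heel point from the *supporting line* of the stride vector
(distance to the line, not the segment — this makes SW ≈ 0 for lateral
gait, where the opposite heel is nearly collinear with the stride).
Each foot's first stride and last two strides are treadmill transition
strides and excluded from summaries. Both metrics are invariant under
vertical-axis rotations and horizontal translations of the world frame,
and ROM is invariant under constant angle offsets — the property that
makes ROM comparable across methods even when absolute angles disagree by
a bias.

## Calibration

The filter consumes, per segment, the anatomical→sensor rotation R_AS;
per joint, center offsets and flexion-axis unit vectors in each adjacent
IMU frame; per foot, a heel offset. These are inputs (in practice from a
motion-capture or functional calibration), not outputs. Helpers cover the
standard construction steps: composing R_AS = R_CS·R_AC with polar-
decomposition re-orthonormalization; recovering a cluster→sensor rotation
from paired angular-velocity streams as the orthogonal Procrustes
minimizer (SVD with det +1, error on collinear input); and a structured
validation report that checks rotation validity, unit axes, offset
magnitudes, and — given a static pose — world-frame axis agreement and
joint-center residuals.

## The synthetic gait simulator

The simulator is the test bed standing in for human-subject data. It
emulates six treadmill gaits in the belt frame (forward slow/normal/fast,
backward, lateral left/right) with belt speeds and stride rates typical
of each (e.g. forward normal 0.86 m/s at 0.79 Hz → 1.09 m strides; lateral
0.39 m/s, 0.48 m strides, near-zero step width), 60 s trials at 128 Hz.

Construction: pelvis pose and the two ankle-point trajectories are
prescribed analytically — foot progression uses quintic smoothstep swing
blends so each foot is *exactly* still (position and orientation constant)
during a stance dwell window covering 35 % of the stride; the knee closes
the chain by exact two-link inverse kinematics between hip and ankle, so
the joint-center constraint holds identically on the analytic chain; foot
swing pitch and optional thigh/shank long-axis twists act about axes
through the joint centers and never disturb it. Feasibility of the leg
triangle (hip-ankle distance vs. thigh+shank length) is checked over the
whole trial at generation time.

IMU synthesis inverts the discrete strapdown step exactly: world
velocities come from complex-step differentiation of the analytic chain
(exact first derivatives, no cancellation), gyro samples from quaternion
increments, accelerometer samples from velocity increments, and the
ground-truth positions are the exact discrete propagation of those
samples. Feeding the noise-free streams back through strapdown
integration therefore reproduces the truth to machine precision — the
strongest correctness oracle for both the simulator and the filter, and
one that analytic differentiation alone cannot provide (a discrete
integrator of a smooth trajectory always carries O(Δt²) remainder). The
discrete positions differ from the analytic chain positions by that same
trapezoid remainder, ~10⁻⁵ m at 128 Hz; the joint-center constraint is
exact on the analytic positions and holds to <5·10⁻⁴ m on the discrete
ones — three orders below the 0.01 m joint-center noise. Sensor noise is
additive white Gaussian (defaults σ_a = 0.013 m/s², σ_ω = 2.83 deg/s)
from a seeded generator; an optional constant gyro bias is off by
default.

Default waveforms respect the premises the filter encodes: the
ground-truth knee is a true hinge (thigh/shank twists default to zero;
hip internal-rotation content arises from pelvis yaw against the leg
plane), and a soft-tissue artifact option (sinusoidal wobble of the thigh
IMU mounting, default off) exists to exercise the model mismatch that
motivates the loose hip axis noise. Waveforms are low-order periodic
shapes chosen for realistic ranges of motion — hip flexion dominant in
forward gait, hip ab/adduction dominant in lateral gait — and are *not*
claimed to reproduce human waveforms. Consequently, passing tests
demonstrate estimator correctness and noise robustness under ideal
calibration and rigid segments; they do not quantify robustness to soft
tissue motion, calibration error, nonstationary belt speed, or
pathological gait variability, which dominate error budgets on real
subjects.

Ground-truth joint angles are computed with scipy's intrinsic-ZXY Euler
decomposition, deliberately independent of the package's own closed-form
decomposition; the two are cross-checked in the tests.

## Numerical choices

* Quaternions are renormalized after every multiply/integration (drift
  tolerance 10⁻⁹); sign is canonicalized (w ≥ 0) only at I/O boundaries,
  never inside the filter, to avoid discontinuities in error injection.
* Zero-angle limits of the exponential map and Rodrigues formula are
  handled by series expansion — no division by zero anywhere.
* P is symmetrized after every predict and update; a negative diagonal
  triggers eigenvalue clamping at −10⁻¹⁰ with a warning.
* The innovation solve uses `cho_factor`/`cho_solve`; on failure a 10⁻¹²
  jitter is added and the condition number logged.
* Complex-step differentiation uses h = 10⁻¹⁰⁰; all simulator chain code
  is written holomorphically (no abs/conj/norm), and piecewise branches
  select on the real part.
* The default detection/test problem sizes are 10 s trials for unit
  tests and a single 60 s trial (7680 samples, 7 IMUs, 63-dimensional
  error state) for the end-to-end accuracy checks; one such filter run
  takes ~15 s in pure numpy.

## Known limitations

* No gyroscope/accelerometer bias states: constant sensor biases are not
  estimated (walking data contains too little still time to observe
  them), and no magnetometer is used; global heading is unobservable and
  drifts slowly — joint angles, SL and SW are invariant to it.
* The hip soft hinge is a modeling convenience; with strongly non-sagittal
  gaits it contributes bias that the loose noise only partially removes.
* Offline, single-threaded batch processing; no real-time operation or
  smoothing (RTS) pass.
* Calibration quality is assumed; errors in R_AS or joint-center offsets
  propagate directly into angle offsets (ROM is largely immune, absolute
  angles are not).
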