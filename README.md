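# gaitkf

**3D lower-limb gait kinematics from a seven-IMU body-worn array, via an
error-state Kalman filter.**

Optical motion capture is the clinical gold standard for gait analysis but
confines studies to a lab. Body-worn inertial measurement units (IMUs) are
cheap and portable, yet integrating their noisy accelerometer and gyroscope
signals drifts within seconds. `gaitkf` implements a magnetometer-free
estimator for the lower limbs — pelvis, both thighs, shanks and feet, one
IMU per segment — that corrects drift with the kinematics of walking
itself, and derives the quantities gait researchers actually use: 3D joint
angles of the hips, knees and ankles, per-stride ranges of motion, stride
length, and step width.

It is aimed at biomechanics and wearable-sensing researchers who want a
transparent, fully testable reference implementation: a synthetic treadmill
gait simulator with exact ground truth (six gaits — forward slow/normal/
fast, backward, lateral left/right) makes every stage of the pipeline
verifiable without any human-subject data.

## The estimator

Each IMU *j* is a free rigid body with nominal state
$x_j = (p_j, v_j, q_j)$ — world-frame position, velocity, and a Hamiltonian
unit quaternion — propagated by strapdown integration at 128 Hz:

$$
p \leftarrow p + v\,\Delta t + \tfrac12 (R a + g)\Delta t^2,\qquad
v \leftarrow v + (R a + g)\Delta t,\qquad
q \leftarrow q \otimes \exp\!\left(\tfrac{\omega \Delta t}{2}\right).
$$

The filter tracks the $9n$-dimensional *error state*
$\delta x = (\delta p, \delta v, \delta\theta)$ per IMU (attitude error
local: $q \leftarrow \hat q \otimes \delta q$), whose mean is identically
zero between updates; only its covariance $P$ is propagated, with
block-diagonal process noise $\sigma_a^2 \Delta t^2$, $\sigma_\omega^2
\Delta t^2$ on the velocity and attitude blocks. Four pseudo-measurements
$z = h(x) + c$, applied in one batch per time step, correct drift:

| correction | expected measurement $h(x)$ | applied | noise σ |
|---|---|---|---|
| ZUPT | $v_{\text{foot}}$ | once per stance, at the footfall | 0.01 m/s |
| gravity tilt | $R^\mathsf{T}[0,0,1]^\mathsf{T}$ | quasi-static samples | 5.73° |
| joint center | $(p_1 + R_1 r_1) - (p_2 + R_2 r_2)$ | every step, all 6 joints | 0.01 m |
| joint axis | $R_1 e_1 - R_2 e_2$ | every step, knees & hips | knee 1.15°, hip 57.3° |

The joint-axis term is a *soft hinge*: it biases (never forces) the
flexion axes of adjacent segments to stay aligned — tight for the knee,
which nearly is a hinge, very loose for the three-degree-of-freedom hip,
and absent for the ankle. After each update the error mean is injected
into the nominal state, reset to zero, and $P$ is mapped through the reset
Jacobian.

Segment orientations follow from the estimated IMU poses through the
sensor-to-segment calibration $R_{AS}$ (plus per-joint center offsets
$r_i$, axis vectors $e_i$, and heel offsets — all inputs, expressed in IMU
frames). Joint angles use the joint-coordinate-system Z-X-Y decomposition
(flexion about the proximal medial-lateral axis, internal rotation about
the distal longitudinal axis, adduction about the floating axis), low-pass
filtered with a zero-lag 4th-order Butterworth at 6 Hz. Stride length is
the horizontal heel displacement between consecutive same-foot footfalls;
step width the perpendicular distance of the intermediate opposite-foot
heel from the stride line.

## Worked example

```python
from gaitkf import (GaitFilterModel, GaitSpec, NoiseConfig,
                    generate_truth, synthesize_imu)

spec = GaitSpec.preset("forward_normal", trial_duration=20.0)   # 0.86 m/s belt
truth = generate_truth(spec)                                    # exact ground truth
acc, gyr = synthesize_imu(truth, noise=NoiseConfig(), seed=0)   # IMU-grade noise

model = GaitFilterModel(acc, gyr, truth.calibration,
                        truth.initial_state(), imu_order=truth.imu_order)
res = model.fit()
print(res.summary())
```

```
Lower-limb error-state Kalman filter results
====================================================
IMUs: 7 (pelvis, thigh_l, thigh_r, shank_l, shank_r, foot_l, foot_r)
Samples: 2560 at 128 Hz (20.0 s)
Measurement corrections applied:
  ZUPT                32
  TILT              1978
  JOINT_CENTER     15360
  JOINT_AXIS       10240
  suppressed tilt events: 0
Footfalls (foot_l): 16
Footfalls (foot_r): 16
Strides (non-transition): 24
  stride length  1.089 ± 0.003 m
  step width     0.119 ± 0.004 m
Mean range of motion per joint angle (deg):
  hip_l     FE      44.1
  hip_l     AbAd     6.9
  ...
```

The estimated stride length (1.089 m) reproduces the simulated belt speed
over stride rate (0.86/0.79 = 1.089 m), step width the simulated 0.12 m
lateral foot separation. Against the simulator's ground truth,

```python
res.angle_rms_error(truth.joint_angles).head(3)
```

```
joint angle  rms_deg
hip_l    FE 0.213119
hip_l  AbAd 0.472735
hip_l    IE 0.626220
```

i.e. sub-degree joint-angle accuracy under sensor noise, while raw
strapdown integration of the same streams drifts by tens of degrees per
minute (`CorrectionToggles.none()` reproduces that contrast).

A command-line interface wraps the same pipeline:

```sh
gaitkf simulate --gait forward_normal --duration 60 --seed 7 --out fixture/
gaitkf run fixture/ --out results/
gaitkf metrics results/
```

Output file formats are documented in [FORMATS.md](FORMATS.md); the model
and its numerical choices in [docs/methods.md](docs/methods.md).

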