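# File formats

All times are seconds from stream start; all internal math is in radians,
but serialized angles are **degrees** and distances **meters**. CSVs use
plain headers, no index column.

## Fixture (written by `gaitkf simulate` / `gaitkf.simulator.emit_fixture`)

| file | contents |
|---|---|
| `imu_<segment>.csv` | `t, ax, ay, az, gx, gy, gz` — specific force (m/s², sensor frame; a stationary level IMU reads `az ≈ +9.81`) and angular velocity (rad/s, sensor frame) |
| `calibration.yaml` | versioned schema: per-segment 3×3 `R_AS` (anatomical→sensor), per-joint `parent/child` segments with `r_parent/r_child` (joint-center offsets, m, IMU frames) and `e_parent/e_child` (flexion-axis unit vectors, IMU frames), per-foot `heel_offsets` |
| `truth.h5` | datasets `t`, `p`, `v`, `q` (N×7×{3,3,4}; quaternions w,x,y,z), `p_analytic`, groups `joint_angles/<joint>` (N×3, deg), `footfalls/<foot>`, `heel/<foot>`; attribute `imu_order` |
| `manifest.yaml` | the generating spec, its SHA-256 digest, seed, noise settings, file list |

Segments: `pelvis, thigh_l, thigh_r, shank_l, shank_r, foot_l, foot_r`.
Joints: `hip_l, hip_r, knee_l, knee_r, ankle_l, ankle_r`.

## Results (written by `gaitkf run` / `gaitkf.io.write_results`)

| file | columns |
|---|---|
| `poses.csv` | `t, imu_id, px, py, pz, vx, vy, vz, qw, qx, qy, qz` |
| `joint_angles.csv` | `t, joint, FE, AbAd, IE` (deg). For the ankles the same three columns carry dorsiflexion/plantarflexion (in `FE`), inversion/eversion (in `AbAd`) and internal/external rotation (in `IE`) |
| `strides.csv` | `foot, start_index, end_index, t_start, t_end, SL, SW, transition` plus per-stride ipsilateral ROM columns `rom_<joint>_<angle>` (deg). `transition` marks each foot's first stride and last two strides, excluded from summaries |
| `heel_trajectories.csv` | `t, foot, x, y, z` (world frame, m) |
| `events.csv` | `imu_id, kind (STILL/FOOTFALL), start_index, end_index` — half-open sample intervals for stills; `start_index == end_index` for footfalls |
| `summary.json` | sample/event counts, footfall counts, stride means, enabled corrections, `prediction_only` flag, and per-angle RMS vs ground truth (`angle_rms_deg`) when the fixture carries truth |

Angle sign conventions: flexion positive about the proximal medial-lateral
axis; adduction and internal rotation positive on both sides (left-side
values are mirrored). World frame: x anterior, y left, z up; gravity is
`[0, 0, −9.81]` m/s².
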