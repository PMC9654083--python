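"""Synthetic seven-segment treadmill gait with exact ground truth.

The generator builds kinematically consistent motion for pelvis, thighs,
shanks and feet, then synthesizes the IMU signals the filter consumes.  It
emulates six treadmill gaits (forward slow/normal/fast, backward, lateral
left/right) in the belt frame, where the subject progresses at belt speed
and each foot is *exactly* still during a stance dwell window.

Construction
------------
Pelvis pose and ankle-point (foot) trajectories are prescribed analytically:
foot progression uses quintic-smoothstep swing blends, so position, velocity
and acceleration are continuous and identically constant during dwell.  The
knee is closed by exact two-link inverse kinematics between hip and ankle,
which keeps the joint-center constraint satisfied identically on the
analytic chain.  Thigh/shank long-axis twists and foot swing pitch are added
about axes through the joint centers, so they never disturb the constraint.

IMU synthesis
-------------
World velocities come from complex-step differentiation of the analytic
chain (exact first derivatives, no cancellation error).  Gyro and
accelerometer samples are then the exact discrete inverse of the strapdown
step: ω_k from the quaternion increment, a_k = Rᵀ(Δv/Δt − g).  Ground-truth
positions are the exact discrete propagation of those samples, so feeding
the noise-free stream back through strapdown integration reproduces the
truth to machine precision.  (The analytic chain positions are also kept;
they satisfy the joint-center constraint to ~1e-12, while the discrete
positions differ from them by the trapezoid-rule remainder, ~1e-5 m at
128 Hz — far below the 0.01 m joint-center measurement noise.)

Gait waveforms are low-order periodic shapes chosen to produce ranges of
motion of realistic magnitude (hip FE dominant for forward gait, hip AbAd
dominant for lateral gait); they are not claimed to reproduce any human
subject's waveforms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .calibration import CalibrationSet
from .erkf import GRAVITY, NoiseConfig, NominalState

__all__ = ["GaitSpec", "GroundTruth", "Anthropometry", "generate_truth",
           "synthesize_imu", "emit_fixture", "SEGMENTS", "FOOT_SEGMENTS"]

SEGMENTS = ["pelvis", "thigh_l", "thigh_r", "shank_l", "shank_r", "foot_l", "foot_r"]
FOOT_SEGMENTS = ["foot_l", "foot_r"]

# neutral anatomical frame in world coords: X anterior(+x), Y up(+z), Z right(−y)
_R0 = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])

_PRESETS = {
    #                 belt m/s, stride Hz, direction, step width m
    "forward_normal": (0.86, 0.79, (1.0, 0.0), 0.12),
    "forward_fast": (1.32, 0.94, (1.0, 0.0), 0.11),
    "forward_slow": (0.47, 0.56, (1.0, 0.0), 0.13),
    "backward": (0.43, 0.69, (-1.0, 0.0), 0.15),
    "lateral_left": (0.39, 0.81, (0.0, 1.0), 0.01),
    "lateral_right": (0.38, 0.83, (0.0, -1.0), 0.01),
}


@dataclass
class Anthropometry:
    """Segment geometry (m).  Hip height is the hip-center height; the
    thigh+shank length minus the hip-to-ankle gap sets the knee flexion
    margin, checked at generation time."""

    hip_half_width: float = 0.09
    thigh_length: float = 0.42
    shank_length: float = 0.43
    hip_height: float = 0.80
    ankle_height: float = 0.08
    heel_anat: tuple = (-0.05, -0.07, 0.0)  # heel point in foot anatomical frame

    # IMU mounting: position in segment anatomical frame
    imu_pos: dict = field(
        default_factory=lambda: {
            "pelvis": (-0.10, 0.05, 0.0),
            "thigh_l": (0.02, -0.20, -0.07),
            "thigh_r": (0.02, -0.20, 0.07),
            "shank_l": (0.02, -0.18, -0.05),
            "shank_r": (0.02, -0.18, 0.05),
            "foot_l": (0.06, 0.02, 0.0),
            "foot_r": (0.06, 0.02, 0.0),
        }
    )
    # mounting rotation R_AS per segment as a rotation vector (rad);
    # deliberately non-trivial so sensor-to-segment alignment is exercised
    imu_rotvec: dict = field(
        default_factory=lambda: {
            "pelvis": (0.30, -0.15, 0.40),
            "thigh_l": (-0.50, 0.25, 0.10),
            "thigh_r": (0.45, -0.20, -0.15),
            "shank_l": (0.20, 0.55, -0.30),
            "shank_r": (-0.25, -0.45, 0.35),
            "foot_l": (0.15, 0.30, 0.50),
            "foot_r": (-0.35, 0.20, -0.40),
        }
    )


@dataclass
class GaitSpec:
    """Parameters of one synthetic treadmill trial.

    Belt speeds and stride rates default to values typical for each gait
    (e.g. forward normal: 0.86 m/s belt, ~1.09 m stride); stride length is
    belt_speed / stride_rate by construction.
    """

    gait_type: str = "forward_normal"
    belt_speed: float = 0.86
    stride_rate: float = 0.79
    trial_duration: float = 60.0
    stance_dwell_fraction: float = 0.35
    fs: float = 128.0
    seed: int = 0
    step_width: float = 0.12
    swing_clearance: float = 0.04
    foot_pitch_deg: float = 12.0
    pelvis_sway: float = 0.02
    pelvis_bob: float = 0.012
    pelvis_yaw_deg: float = 3.0
    pelvis_roll_deg: float = 2.0
    # long-axis twists of thigh/shank: zero by default so the ground-truth
    # knee is a true hinge (the premise the soft-hinge correction encodes);
    # hip internal rotation content still arises from pelvis yaw against
    # the leg plane.  Nonzero values deliberately violate the hinge.
    twist_thigh_deg: float = 0.0
    twist_shank_deg: float = 0.0
    # soft-tissue artifact: sinusoidal wobble of the thigh IMU mounting
    # about its anatomical anterior axis (orientation only), exercising the
    # model mismatch that motivates the loose hip joint-axis noise.
    sta_thigh_deg: float = 0.0
    anthropometry: Anthropometry = field(default_factory=Anthropometry)

    def __post_init__(self) -> None:
        if self.gait_type not in _PRESETS:
            raise ValueError(
                f"unknown gait_type {self.gait_type!r}; choose from {sorted(_PRESETS)}"
            )
        if self.belt_speed <= 0:
            raise ValueError("belt_speed must be positive")
        if not (0.0 < self.stance_dwell_fraction < 1.0):
            raise ValueError("stance_dwell_fraction must lie in (0, 1)")
        if self.stride_rate * self.trial_duration < 4:
            raise ValueError("trial must contain at least 4 strides")

    @classmethod
    def preset(cls, gait_type: str, **overrides) -> "GaitSpec":
        if gait_type not in _PRESETS:
            raise ValueError(
                f"unknown gait_type {gait_type!r}; choose from {sorted(_PRESETS)}"
            )
        belt, rate, _, sw = _PRESETS[gait_type]
        kwargs = dict(gait_type=gait_type, belt_speed=belt, stride_rate=rate, step_width=sw)
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def stride_length(self) -> float:
        return self.belt_speed / self.stride_rate

    def direction(self) -> np.ndarray:
        dx, dy = _PRESETS[self.gait_type][2]
        return np.array([dx, dy, 0.0])

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(asdict(self))

    def digest(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# --------------------------------------------------------------------------
# complex-safe primitives (complex-step differentiation flows through these)
# --------------------------------------------------------------------------


def _vnorm(v):
    return np.sqrt(np.sum(v * v, axis=-1))


def _unit(v):
    return v / _vnorm(v)[..., None]


def _smoothstep(tau):
    """Quintic smoothstep: value 0→1 with zero 1st/2nd derivatives at ends."""
    return tau**3 * (6.0 * tau * tau - 15.0 * tau + 10.0)


def _bump(tau):
    """C² bump, 0 at the ends (with zero 1st/2nd derivatives), peak 1."""
    return 64.0 * (tau * (1.0 - tau)) ** 3


def _axis_rotation(axis: np.ndarray, angle):
    """Rotation about a fixed unit axis; angle may be a (complex) array.

    Rodrigues form, holomorphic in the angle so complex-step derivatives
    pass through exactly.
    """
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    angle = np.asarray(angle)
    I = np.eye(3)
    sa = np.sin(angle)[..., None, None]
    ca = np.cos(angle)[..., None, None]
    return I + sa * K + (1.0 - ca) * (K @ K)


def _foot_progression(t, spec: GaitSpec, offset: float):
    """Progression coordinate, height and swing phase of one ankle point.

    Returns (s, z, tau, in_swing) where s is the signed distance along the
    progression direction, z the ankle height, tau the swing phase in [0,1]
    (0 during dwell) and in_swing a boolean mask.  Piecewise in the stride
    phase; branch selection uses the real part so complex-step evaluation
    stays on the correct branch.
    """
    T = 1.0 / spec.stride_rate
    d = spec.stance_dwell_fraction
    SL = spec.stride_length
    phi = t / T - offset
    m = np.floor(np.real(phi))
    c = phi - m
    in_swing = np.real(c) >= d
    tau = np.where(in_swing, (c - d) / (1.0 - d), 0.0 * c)
    s_plant = SL * (m + offset + 0.5 * d)
    s = s_plant + np.where(in_swing, SL * _smoothstep(tau), 0.0 * tau)
    z = spec.anthropometry.ankle_height + np.where(
        in_swing, spec.swing_clearance * _bump(tau), 0.0 * tau
    )
    return s, z, tau, in_swing


def _chain(t, spec: GaitSpec):
    """Evaluate the full analytic kinematic chain at (possibly complex) t.

    Returns dict segment → (origin (N,3), R_WA (N,3,3)).
    """
    a = spec.anthropometry
    T = 1.0 / spec.stride_rate
    u = spec.direction()
    u_perp = np.array([-u[1], u[0], 0.0])
    omega0 = 2.0 * np.pi / T
    t = np.asarray(t)
    N = t.shape[0]
    zhat = np.array([0.0, 0.0, 1.0])
    xhat = np.array([1.0, 0.0, 0.0])

    out: dict[str, tuple] = {}

    # pelvis
    sway = spec.pelvis_sway * np.sin(omega0 * t)
    bob = spec.pelvis_bob * np.sin(2.0 * omega0 * t + 0.4)
    o_p = (
        (spec.belt_speed * t)[:, None] * u
        + sway[:, None] * u_perp
        + (a.hip_height + bob)[:, None] * zhat
    )
    yaw = np.deg2rad(spec.pelvis_yaw_deg) * np.sin(omega0 * t)
    roll = np.deg2rad(spec.pelvis_roll_deg) * np.sin(omega0 * t + 0.5 * np.pi)
    R_p = _axis_rotation(zhat, yaw) @ _axis_rotation(xhat, roll) @ _R0
    out["pelvis"] = (o_p, R_p)

    for side, sgn, offset in (("l", -1.0, 0.0), ("r", 1.0, 0.5)):
        # hip center (anatomical Z points right; left hip at −hw)
        hip = o_p + (R_p @ np.array([0.0, 0.0, sgn * a.hip_half_width]))
        # ankle point
        s, z, tau, in_swing = _foot_progression(t, spec, offset)
        # lateral placement: for forward/backward gait feet sit at ±half
        # step width along world y (left foot +y); for lateral gait the
        # offset is along the (perpendicular) anterior axis instead.
        if u[0] != 0.0:
            lat_dir = np.array([0.0, 1.0, 0.0])
            lat_off = -sgn * 0.5 * spec.step_width
        else:
            lat_dir = np.array([1.0, 0.0, 0.0])
            lat_off = sgn * 0.5 * spec.step_width
        ankle = s[:, None] * u + lat_off * lat_dir[None, :] + z[:, None] * zhat

        # foot orientation: neutral during stance, pitch bump during swing
        pitch = (
            np.deg2rad(spec.foot_pitch_deg)
            * np.sin(2.0 * np.pi * tau)
            * _bump(tau)
        )
        flex_axis = np.array([0.0, -1.0, 0.0])  # medial-lateral (to the right)
        R_foot = _axis_rotation(flex_axis, pitch) @ _R0

        # two-link inverse kinematics for the knee
        dvec = ankle - hip
        D = _vnorm(dvec)
        dhat = dvec / D[..., None]
        L1, L2 = a.thigh_length, a.shank_length
        cos_alpha = (L1 * L1 + D * D - L2 * L2) / (2.0 * L1 * D)
        sin_alpha = np.sqrt(1.0 - cos_alpha * cos_alpha)
        fwd = xhat - (dhat @ xhat)[..., None] * dhat
        chat = _unit(fwd)
        knee = hip + L1 * (cos_alpha[..., None] * dhat + sin_alpha[..., None] * chat)

        # thigh and shank frames: Y up the segment, Z the flexion plane
        # normal (pointing right), X anterior
        Zax = _unit(np.cross(ankle - knee, knee - hip))
        Y_t = (hip - knee) / L1
        X_t = np.cross(Y_t, Zax)
        R_thigh = np.stack([X_t, Y_t, Zax], axis=-1)
        Y_s = (knee - ankle) / L2
        X_s = np.cross(Y_s, Zax)
        R_shank = np.stack([X_s, Y_s, Zax], axis=-1)

        # long-axis twists (hip/knee internal rotation content); the
        # rotation axis passes through both joint centers of the segment,
        # so joint positions are untouched
        tw_t = np.deg2rad(spec.twist_thigh_deg) * np.sin(omega0 * t + (0.3 if sgn > 0 else 1.1))
        tw_s = np.deg2rad(spec.twist_shank_deg) * np.sin(omega0 * t + (1.9 if sgn > 0 else 0.7))
        R_thigh = R_thigh @ _axis_rotation(np.array([0.0, 1.0, 0.0]), tw_t)
        R_shank = R_shank @ _axis_rotation(np.array([0.0, 1.0, 0.0]), tw_s)

        out[f"thigh_{side}"] = (hip, R_thigh)
        out[f"shank_{side}"] = (knee, R_shank)
        out[f"foot_{side}"] = (ankle, R_foot)
    return out


def _build_calibration(spec: GaitSpec) -> CalibrationSet:
    """Calibration consistent with the chain geometry, in IMU frames."""
    a = spec.anthropometry
    R_AS = {
        seg: Rotation.from_rotvec(a.imu_rotvec[seg]).as_matrix() for seg in SEGMENTS
    }
    c = {seg: np.asarray(a.imu_pos[seg], dtype=float) for seg in SEGMENTS}

    def offs(seg: str, point_anat: np.ndarray) -> np.ndarray:
        return R_AS[seg] @ (np.asarray(point_anat, dtype=float) - c[seg])

    zaxis = np.array([0.0, 0.0, 1.0])
    joints: dict[str, dict] = {}
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        hip_in_pelvis = np.array([0.0, 0.0, sgn * a.hip_half_width])
        joints[f"hip_{side}"] = {
            "parent": "pelvis",
            "child": f"thigh_{side}",
            "r_parent": offs("pelvis", hip_in_pelvis),
            "r_child": offs(f"thigh_{side}", np.zeros(3)),
            "e_parent": R_AS["pelvis"] @ zaxis,
            "e_child": R_AS[f"thigh_{side}"] @ zaxis,
        }
        joints[f"knee_{side}"] = {
            "parent": f"thigh_{side}",
            "child": f"shank_{side}",
            "r_parent": offs(f"thigh_{side}", np.array([0.0, -a.thigh_length, 0.0])),
            "r_child": offs(f"shank_{side}", np.zeros(3)),
            "e_parent": R_AS[f"thigh_{side}"] @ zaxis,
            "e_child": R_AS[f"shank_{side}"] @ zaxis,
        }
        joints[f"ankle_{side}"] = {
            "parent": f"shank_{side}",
            "child": f"foot_{side}",
            "r_parent": offs(f"shank_{side}", np.array([0.0, -a.shank_length, 0.0])),
            "r_child": offs(f"foot_{side}", np.zeros(3)),
            "e_parent": R_AS[f"shank_{side}"] @ zaxis,
            "e_child": R_AS[f"foot_{side}"] @ zaxis,
        }
    heel = {
        f"foot_{s}": offs(f"foot_{s}", np.asarray(a.heel_anat)) for s in ("l", "r")
    }
    return CalibrationSet(R_AS=R_AS, joints=joints, heel_offsets=heel)


@dataclass
class GroundTruth:
    """Exact reference motion for one synthetic trial.

    ``p`` is round-trip exact under strapdown integration of the noise-free
    synthesized IMU stream; ``p_analytic`` are the analytic chain positions
    (joint-center constraint exact).  ``joint_angles`` maps joint name →
    (N, 3) degrees in (flexion, adduction, internal-rotation) order with
    left-side sign mirroring applied.
    """

    spec: GaitSpec
    t: np.ndarray
    imu_order: list[str]
    p: np.ndarray  # (N, 7, 3)
    v: np.ndarray  # (N, 7, 3)
    q: np.ndarray  # (N, 7, 4) wxyz
    p_analytic: np.ndarray
    joint_angles: dict[str, np.ndarray]
    dwell_windows: dict[str, list[tuple[int, int]]]
    footfalls: dict[str, np.ndarray]
    heel: dict[str, np.ndarray]
    calibration: CalibrationSet

    @property
    def fs(self) -> float:
        return self.spec.fs

    def initial_state(self) -> NominalState:
        return NominalState(self.p[0].copy(), self.v[0].copy(), self.q[0].copy())


def _truth_joint_angles(frames: dict) -> dict[str, np.ndarray]:
    """ZXY intrinsic decomposition of each joint's relative rotation
    (scipy), with left-side AbAd/IE sign mirroring."""
    pairs = [
        ("hip_l", "pelvis", "thigh_l", "L"),
        ("hip_r", "pelvis", "thigh_r", "R"),
        ("knee_l", "thigh_l", "shank_l", "L"),
        ("knee_r", "thigh_r", "shank_r", "R"),
        ("ankle_l", "shank_l", "foot_l", "L"),
        ("ankle_r", "shank_r", "foot_r", "R"),
    ]
    out = {}
    for joint, prox, dist, side in pairs:
        Rp = frames[prox][1]
        Rd = frames[dist][1]
        rel = np.einsum("nji,njk->nik", Rp, Rd)
        ang = Rotation.from_matrix(rel).as_euler("ZXY", degrees=True)
        if side == "L":
            ang = ang * np.array([1.0, -1.0, -1.0])
        out[joint] = ang
    return out


def generate_truth(spec: GaitSpec) -> GroundTruth:
    """Build the exact reference motion and calibration for one trial."""
    a = spec.anthropometry
    fs = spec.fs
    N = int(round(spec.trial_duration * fs))
    t = np.arange(N) / fs
    dt = 1.0 / fs

    frames = _chain(t, spec)

    # feasibility of the leg geometry over the whole trial
    for side in ("l", "r"):
        hip = frames[f"thigh_{side}"][0]
        ankle = frames[f"foot_{side}"][0]
        D = np.linalg.norm(ankle - hip, axis=-1)
        reach = a.thigh_length + a.shank_length
        if D.max() > 0.98 * reach or D.min() < 0.3 * reach:
            raise ValueError(
                f"gait spec kinematically infeasible: hip-ankle distance range "
                f"[{D.min():.3f}, {D.max():.3f}] m versus leg length {reach:.3f} m"
            )

    calib = _build_calibration(spec)
    c_pos = {seg: np.asarray(a.imu_pos[seg], dtype=float) for seg in SEGMENTS}

    # IMU poses on the analytic chain
    p_analytic = np.empty((N, len(SEGMENTS), 3))
    q = np.empty((N, len(SEGMENTS), 4))
    for j, seg in enumerate(SEGMENTS):
        origin, R_WA = frames[seg]
        if spec.sta_thigh_deg and seg.startswith("thigh"):
            # soft-tissue wobble of the mounting (orientation only); the
            # filter still consumes the nominal, time-invariant R_AS
            theta = np.deg2rad(spec.sta_thigh_deg) * np.sin(
                2.0 * np.pi * spec.stride_rate * t + (0.2 if seg.endswith("r") else 1.4)
            )
            wobble = _axis_rotation(np.array([1.0, 0.0, 0.0]), -theta)
            R_WS = R_WA @ wobble @ calib.R_AS[seg].T
        else:
            R_WS = R_WA @ calib.R_AS[seg].T
        p_analytic[:, j] = origin + np.einsum("nij,j->ni", R_WA, c_pos[seg])
        qs = Rotation.from_matrix(R_WS).as_quat()  # xyzw
        qs = np.roll(qs, 1, axis=1)
        # enforce temporal sign continuity for smooth gyro extraction
        flips = np.cumsum(np.sum(qs[1:] * qs[:-1], axis=1) < 0) % 2
        qs[1:][flips == 1] *= -1.0
        q[:, j] = qs

    # exact world velocities via complex-step differentiation
    h = 1e-100
    frames_c = _chain(t + 1j * h, spec)
    v = np.empty((N, len(SEGMENTS), 3))
    for j, seg in enumerate(SEGMENTS):
        origin_c, R_WA_c = frames_c[seg]
        p_c = origin_c + np.einsum("nij,j->ni", R_WA_c, c_pos[seg])
        v[:, j] = np.imag(p_c) / h

    # ground-truth positions: exact discrete propagation of the synthesized
    # stream, i.e. trapezoidal accumulation of the exact velocities
    p = np.empty_like(p_analytic)
    p[0] = p_analytic[0]
    increments = 0.5 * (v[:-1] + v[1:]) * dt
    p[1:] = p[0] + np.cumsum(increments, axis=0)

    # dwell windows and footfall instants (exact, from the stride phase)
    T = 1.0 / spec.stride_rate
    d = spec.stance_dwell_fraction
    dwell: dict[str, list[tuple[int, int]]] = {}
    footfalls: dict[str, np.ndarray] = {}
    for seg, offset in (("foot_l", 0.0), ("foot_r", 0.5)):
        windows = []
        ffs = []
        m = int(np.floor(-offset)) - 1
        while True:
            t_start = (m + offset) * T
            t_end = (m + offset + d) * T
            if t_start >= t[-1]:
                break
            lo = max(int(np.ceil(t_start * fs)), 0)
            hi = min(int(np.floor(t_end * fs)) + 1, N)
            if hi - lo > 0 and lo < N:
                windows.append((lo, hi))
                mid = int(round((t_start + 0.5 * d * T) * fs))
                if 0 <= mid < N:
                    ffs.append(mid)
            m += 1
        dwell[seg] = windows
        footfalls[seg] = np.asarray(ffs, dtype=int)

    heel = {}
    for seg in FOOT_SEGMENTS:
        j = SEGMENTS.index(seg)
        R_WS = Rotation.from_quat(np.roll(q[:, j], -1, axis=1)).as_matrix()
        heel[seg] = p[:, j] + np.einsum("nij,j->ni", R_WS, calib.heel_offsets[seg])

    return GroundTruth(
        spec=spec,
        t=t,
        imu_order=list(SEGMENTS),
        p=p,
        v=v,
        q=q,
        p_analytic=p_analytic,
        joint_angles=_truth_joint_angles(frames),
        dwell_windows=dwell,
        footfalls=footfalls,
        heel=heel,
        calibration=calib,
    )


def neutral_static_pose(spec: GaitSpec | None = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """IMU poses in a neutral standing posture (all anatomical frames
    world-aligned), for static calibration checks: segment → (p_imu, R_WS)."""
    spec = spec if spec is not None else GaitSpec()
    a = spec.anthropometry
    calib = _build_calibration(spec)
    origins = {"pelvis": np.array([0.0, 0.0, a.hip_height])}
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        hip = origins["pelvis"] + _R0 @ np.array([0.0, 0.0, sgn * a.hip_half_width])
        knee = hip + _R0 @ np.array([0.0, -a.thigh_length, 0.0])
        ankle = knee + _R0 @ np.array([0.0, -a.shank_length, 0.0])
        origins[f"thigh_{side}"] = hip
        origins[f"shank_{side}"] = knee
        origins[f"foot_{side}"] = ankle
    out = {}
    for seg in SEGMENTS:
        p_imu = origins[seg] + _R0 @ np.asarray(a.imu_pos[seg], dtype=float)
        out[seg] = (p_imu, _R0 @ calib.R_AS[seg].T)
    return out


def synthesize_imu(
    truth: GroundTruth,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
    gyro_bias: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize accelerometer/gyroscope streams from ground truth.

    Returns ``(acc, gyr)`` of shape (N, 7, 3): specific force in m/s² (a
    stationary level IMU reads [0, 0, +9.81]) and angular velocity in
    rad/s, both in the sensor frame.  The samples are the exact discrete
    inverse of the strapdown step, so noise-free streams integrate back to
    the truth exactly.  With a :class:`NoiseConfig`, additive white Gaussian
    noise (σ_a, σ_ω) is drawn from a generator seeded by ``seed``.
    """
    N, n = truth.p.shape[0], truth.p.shape[1]
    dt = 1.0 / truth.fs
    acc = np.empty((N, n, 3))
    gyr = np.empty((N, n, 3))
    for j in range(n):
        qs = np.roll(truth.q[:, j], -1, axis=1)  # to scipy xyzw
        rot = Rotation.from_quat(qs)
        rel = rot[:-1].inv() * rot[1:]
        gyr[:-1, j] = rel.as_rotvec() / dt
        gyr[-1, j] = gyr[-2, j]
        R = rot.as_matrix()
        dv = (truth.v[1:, j] - truth.v[:-1, j]) / dt
        acc[:-1, j] = np.einsum("nji,nj->ni", R[:-1], dv - GRAVITY)
        acc[-1, j] = np.einsum("ji,j->i", R[-1], -GRAVITY)
    if noise is not None:
        rng = np.random.default_rng(seed)
        acc = acc + rng.normal(0.0, noise.sigma_a, acc.shape)
        gyr = gyr + rng.normal(0.0, noise.sigma_w, gyr.shape)
    if gyro_bias is not None:
        gyr = gyr + np.asarray(gyro_bias, dtype=float)
    return acc, gyr


def emit_fixture(
    spec: GaitSpec,
    out_dir: str | Path,
    noise: NoiseConfig | None = None,
) -> Path:
    """Write a complete trial fixture: IMU CSVs, calibration, truth, manifest.

    Layout: ``imu_<segment>.csv`` (t, ax, ay, az, gx, gy, gz),
    ``calibration.yaml``, ``truth.h5``, ``manifest.yaml``.  Returns the
    manifest path.  Regeneration from the same spec is bit-identical.
    """
    import h5py

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(spec)
    acc, gyr = synthesize_imu(truth, noise=noise, seed=spec.seed)

    for j, seg in enumerate(truth.imu_order):
        data = np.column_stack([truth.t, acc[:, j], gyr[:, j]])
        header = "t,ax,ay,az,gx,gy,gz"
        np.savetxt(out / f"imu_{seg}.csv", data, delimiter=",", header=header,
                   comments="", fmt="%.12g")

    truth.calibration.to_yaml(out / "calibration.yaml")

    with h5py.File(out / "truth.h5", "w") as f:
        f.create_dataset("t", data=truth.t)
        f.create_dataset("p", data=truth.p)
        f.create_dataset("v", data=truth.v)
        f.create_dataset("q", data=truth.q)
        f.create_dataset("p_analytic", data=truth.p_analytic)
        f.attrs["imu_order"] = ",".join(truth.imu_order)
        grp = f.create_group("joint_angles")
        for joint, ang in truth.joint_angles.items():
            grp.create_dataset(joint, data=ang)
        ffg = f.create_group("footfalls")
        for seg, idx in truth.footfalls.items():
            ffg.create_dataset(seg, data=idx)
        hg = f.create_group("heel")
        for seg, tr in truth.heel.items():
            hg.create_dataset(seg, data=tr)

    manifest = {
        "spec": spec.to_dict(),
        "spec_sha256": spec.digest(),
        "seed": spec.seed,
        "noisy": noise is not None,
        "noise": noise.to_dict() if noise is not None else None,
        "files": sorted(
            str(pp.name) for pp in out.iterdir() if pp.name != "manifest.yaml"
        ),
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path
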