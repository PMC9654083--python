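"""Error-state Kalman filter for an array of body-worn IMUs.

Each IMU is a free rigid body with nominal state (p, v, q) propagated by
strapdown integration of its accelerometer/gyroscope samples.  The filter
tracks a 9·n dimensional error state (δp, δv, δθ per IMU, attitude error
local/right-multiplicative: q ← q ⊗ δq) whose mean is identically zero
between updates; only its covariance P is propagated.  Four pseudo-
measurements correct drift:

* ``ZUPT`` — a foot IMU has zero velocity at a detected footfall;
* ``TILT`` — a still IMU's accelerometer direction equals gravity's;
* ``JOINT_CENTER`` — adjacent segments agree on the world location of
  their shared joint center (applied at every step for every joint);
* ``JOINT_AXIS`` — flexion axes of adjacent segments stay aligned, a
  "soft hinge" applied at every step with a joint-specific noise (tight
  for the knee, very loose for the hip, none for the ankle).

All same-timestep measurements are stacked and applied in one batch
update, after which the error mean is injected into the nominal state,
reset to zero, and the covariance mapped through the reset Jacobian G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .so3 import (
    quat_multiply,
    quat_to_matrix,
    rodrigues,
    rotvec_to_quat,
    skew,
)

__all__ = [
    "NoiseConfig",
    "NominalState",
    "MeasurementEvent",
    "CorrectionToggles",
    "JointSpec",
    "FilterDivergence",
    "predict_state",
    "process_jacobian",
    "process_noise",
    "predict_covariance",
    "make_zupt",
    "make_tilt",
    "make_joint_center",
    "make_joint_axis",
    "batch_update",
    "initial_covariance",
    "run_filter",
    "FilterResult",
]

GRAVITY = np.array([0.0, 0.0, -9.81])


@dataclass
class NoiseConfig:
    """Process and measurement noise standard deviations (SI units).

    Defaults are the values used for a 128 Hz seven-IMU lower-limb array:
    accelerometer 0.013 m/s², gyroscope 2.83 deg/s, zero-velocity 0.01 m/s,
    gravitational tilt 5.73 deg, joint center 0.01 m, knee joint axis
    1.15 deg, hip joint axis 57.3 deg.  Angular quantities are stored in
    radians internally; degree-valued config files are converted on load.
    """

    sigma_a: float = 0.013
    sigma_w: float = float(np.deg2rad(2.83))
    sigma_zupt: float = 0.01
    sigma_tilt: float = float(np.deg2rad(5.73))
    sigma_jc: float = 0.01
    sigma_ja_knee: float = float(np.deg2rad(1.15))
    sigma_ja_hip: float = float(np.deg2rad(57.3))
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    # initial error-state uncertainty; see docs/methods.md for the choice
    sigma_p0: float = 0.01
    sigma_v0: float = 0.01
    sigma_th0: float = float(np.deg2rad(1.0))

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float)
        for name in (
            "sigma_a",
            "sigma_w",
            "sigma_zupt",
            "sigma_tilt",
            "sigma_jc",
            "sigma_ja_knee",
            "sigma_ja_hip",
            "sigma_p0",
            "sigma_v0",
            "sigma_th0",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        """Serializable form; angular sigmas expressed in degrees."""
        return {
            "sigma_a": self.sigma_a,
            "sigma_w_deg": float(np.rad2deg(self.sigma_w)),
            "sigma_zupt": self.sigma_zupt,
            "sigma_tilt_deg": float(np.rad2deg(self.sigma_tilt)),
            "sigma_jc": self.sigma_jc,
            "sigma_ja_knee_deg": float(np.rad2deg(self.sigma_ja_knee)),
            "sigma_ja_hip_deg": float(np.rad2deg(self.sigma_ja_hip)),
            "gravity": [float(x) for x in self.gravity],
            "sigma_p0": self.sigma_p0,
            "sigma_v0": self.sigma_v0,
            "sigma_th0_deg": float(np.rad2deg(self.sigma_th0)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseConfig":
        kwargs: dict = {}
        for key, value in d.items():
            if key.endswith("_deg"):
                kwargs[key[:-4]] = float(np.deg2rad(value))
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class NominalState:
    """Concatenated nominal states of n IMUs: p, v in world frame, unit q."""

    p: np.ndarray  # (n, 3) m
    v: np.ndarray  # (n, 3) m/s
    q: np.ndarray  # (n, 4) wxyz

    def __post_init__(self) -> None:
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        if not (self.p.shape == self.v.shape and self.p.shape[0] == self.q.shape[0]):
            raise ValueError("inconsistent state shapes")

    @property
    def n_imus(self) -> int:
        return self.p.shape[0]

    def rotation(self, j: int) -> np.ndarray:
        return quat_to_matrix(self.q[j])

    def copy(self) -> "NominalState":
        return NominalState(self.p.copy(), self.v.copy(), self.q.copy())


class FilterDivergence(RuntimeError):
    """Raised when the state becomes non-finite; carries the failing step."""

    def __init__(self, step: int, last_good: NominalState):
        super().__init__(f"non-finite state at step {step}")
        self.step = step
        self.last_good = last_good


def predict_state(
    x: NominalState,
    acc: np.ndarray,
    gyr: np.ndarray,
    dt: float,
    noise: NoiseConfig | None = None,
) -> NominalState:
    """One strapdown step per IMU.

    p ← p + vΔt + ½(Ra + g)Δt²;  v ← v + (Ra + g)Δt;
    q ← q ⊗ exp(ωΔt).  IMUs propagate independently.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = noise.gravity if noise is not None else GRAVITY
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    gyr = np.atleast_2d(np.asarray(gyr, dtype=float))
    n = x.n_imus
    p = np.empty_like(x.p)
    v = np.empty_like(x.v)
    q = np.empty_like(x.q)
    for j in range(n):
        if not (np.all(np.isfinite(acc[j])) and np.all(np.isfinite(gyr[j]))):
            raise ValueError(f"non-finite IMU sample for IMU index {j}")
        R = quat_to_matrix(x.q[j])
        a_world = R @ acc[j] + g
        p[j] = x.p[j] + x.v[j] * dt + 0.5 * a_world * dt * dt
        v[j] = x.v[j] + a_world * dt
        q[j] = quat_multiply(x.q[j], rotvec_to_quat(gyr[j] * dt))
    return NominalState(p, v, q)


def process_jacobian(x: NominalState, acc: np.ndarray, gyr: np.ndarray, dt: float) -> np.ndarray:
    """Jacobian of the strapdown step w.r.t. the 9n error state.

    Block diagonal over IMUs; each 9×9 block is

        [ I   ΔtI   −½R[a]ₓΔt² ]
        [ 0    I    −R[a]ₓΔt   ]
        [ 0    0    S{ωΔt}ᵀ    ]

    The position/attitude coupling −½R[a]ₓΔt² is the exact linearization of
    the ½(Ra+g)Δt² position term (negligible at 128 Hz but kept so the
    Jacobian matches finite differences of the step to machine precision).
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    gyr = np.atleast_2d(np.asarray(gyr, dtype=float))
    n = x.n_imus
    F = np.zeros((9 * n, 9 * n))
    I3 = np.eye(3)
    for j in range(n):
        R = quat_to_matrix(x.q[j])
        Ra_x = R @ skew(acc[j])
        b = 9 * j
        F[b : b + 3, b : b + 3] = I3
        F[b : b + 3, b + 3 : b + 6] = dt * I3
        F[b : b + 3, b + 6 : b + 9] = -0.5 * Ra_x * dt * dt
        F[b + 3 : b + 6, b + 3 : b + 6] = I3
        F[b + 3 : b + 6, b + 6 : b + 9] = -Ra_x * dt
        F[b + 6 : b + 9, b + 6 : b + 9] = rodrigues(gyr[j] * dt).T
    return F


def process_noise(noise: NoiseConfig, dt: float, n_imus: int) -> np.ndarray:
    """Block-diagonal Q: zero on position, σ²Δt² on velocity and attitude."""
    qdiag = np.concatenate(
        [
            np.zeros(3),
            np.full(3, noise.sigma_a**2 * dt * dt),
            np.full(3, noise.sigma_w**2 * dt * dt),
        ]
    )
    return np.diag(np.tile(qdiag, n_imus))


def _clamp_psd(P: np.ndarray, floor: float = -1e-10) -> np.ndarray:
    w, V = np.linalg.eigh(P)
    if w.min() >= floor:
        return P
    warnings.warn(
        f"covariance has eigenvalue {w.min():.3e} below {floor:.0e}; clamping",
        RuntimeWarning,
        stacklevel=3,
    )
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T


def predict_covariance(
    P: np.ndarray, Fx: np.ndarray, noise: NoiseConfig, dt: float
) -> np.ndarray:
    """P ← Fx P Fxᵀ + Q, symmetrized."""
    P = np.asarray(P, dtype=float)
    if np.diag(P).min() < -1e-10:
        P = _clamp_psd(P)
    n_imus = P.shape[0] // 9
    Q = process_noise(noise, dt, n_imus)
    out = Fx @ P @ Fx.T + Q
    return 0.5 * (out + out.T)


# --------------------------------------------------------------------------
# Measurement events
# --------------------------------------------------------------------------

_UP_TOL = (0.8, 1.2)  # accepted band of ‖a‖/g for a tilt event


@dataclass
class MeasurementEvent:
    """One 3-vector pseudo-measurement z = h(x) + c, cov(c) = C = σ²I.

    ``imu_indices`` holds one index (ZUPT, TILT) or two (JOINT_CENTER,
    JOINT_AXIS).  ``payload`` carries the calibration vectors (rᵢ or eᵢ)
    the expected-measurement function needs.
    """

    kind: str
    imu_indices: tuple[int, ...]
    z: np.ndarray
    C: np.ndarray
    payload: tuple[np.ndarray, ...] = ()

    def expected(self, x: NominalState) -> np.ndarray:
        if self.kind == "ZUPT":
            return x.v[self.imu_indices[0]].copy()
        if self.kind == "TILT":
            R = x.rotation(self.imu_indices[0])
            return R.T @ self.payload[0]  # payload: world up unit vector
        if self.kind == "JOINT_CENTER":
            i1, i2 = self.imu_indices
            r1, r2 = self.payload
            return (x.p[i1] + x.rotation(i1) @ r1) - (x.p[i2] + x.rotation(i2) @ r2)
        if self.kind == "JOINT_AXIS":
            i1, i2 = self.imu_indices
            e1, e2 = self.payload
            return x.rotation(i1) @ e1 - x.rotation(i2) @ e2
        raise ValueError(f"unknown event kind {self.kind!r}")

    def innovation(self, x: NominalState) -> np.ndarray:
        return self.z - self.expected(x)

    def jacobian(self, x: NominalState) -> np.ndarray:
        """Dense (3, 9n) Jacobian w.r.t. the error state (local attitude
        perturbation R ← R(I + [δθ]ₓ))."""
        n = x.n_imus
        H = np.zeros((3, 9 * n))
        if self.kind == "ZUPT":
            j = self.imu_indices[0]
            H[:, 9 * j + 3 : 9 * j + 6] = np.eye(3)
        elif self.kind == "TILT":
            j = self.imu_indices[0]
            R = x.rotation(j)
            H[:, 9 * j + 6 : 9 * j + 9] = skew(R.T @ self.payload[0])
        elif self.kind == "JOINT_CENTER":
            i1, i2 = self.imu_indices
            r1, r2 = self.payload
            H[:, 9 * i1 : 9 * i1 + 3] = np.eye(3)
            H[:, 9 * i1 + 6 : 9 * i1 + 9] = -x.rotation(i1) @ skew(r1)
            H[:, 9 * i2 : 9 * i2 + 3] = -np.eye(3)
            H[:, 9 * i2 + 6 : 9 * i2 + 9] = x.rotation(i2) @ skew(r2)
        elif self.kind == "JOINT_AXIS":
            i1, i2 = self.imu_indices
            e1, e2 = self.payload
            H[:, 9 * i1 + 6 : 9 * i1 + 9] = -x.rotation(i1) @ skew(e1)
            H[:, 9 * i2 + 6 : 9 * i2 + 9] = x.rotation(i2) @ skew(e2)
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")
        return H


def make_zupt(
    imu: int, noise: NoiseConfig, foot_imus: Iterable[int] | None = None
) -> MeasurementEvent:
    """Zero-velocity pseudo-measurement for a foot IMU at a footfall."""
    if foot_imus is not None and imu not in set(foot_imus):
        raise ValueError(f"ZUPT requested for non-foot IMU {imu}")
    return MeasurementEvent(
        kind="ZUPT",
        imu_indices=(imu,),
        z=np.zeros(3),
        C=noise.sigma_zupt**2 * np.eye(3),
    )


def make_tilt(imu: int, a_meas: np.ndarray, noise: NoiseConfig) -> MeasurementEvent | None:
    """Gravity-direction pseudo-measurement for a still IMU.

    Returns ``None`` (event suppressed) when the accelerometer magnitude is
    outside [0.8 g, 1.2 g], i.e. contaminated by dynamic acceleration.
    """
    a_meas = np.asarray(a_meas, dtype=float)
    norm = float(np.linalg.norm(a_meas))
    if norm <= 0:
        raise ValueError("tilt measurement requires non-zero acceleration")
    gmag = float(np.linalg.norm(noise.gravity))
    if not (_UP_TOL[0] * gmag <= norm <= _UP_TOL[1] * gmag):
        return None
    up = -noise.gravity / gmag
    return MeasurementEvent(
        kind="TILT",
        imu_indices=(imu,),
        z=a_meas / norm,
        C=noise.sigma_tilt**2 * np.eye(3),
        payload=(up,),
    )


def make_joint_center(
    imu1: int, imu2: int, r1: np.ndarray, r2: np.ndarray, noise: NoiseConfig
) -> MeasurementEvent:
    """Joint-center coincidence pseudo-measurement for adjacent segments."""
    if imu1 == imu2:
        raise ValueError("joint center requires two distinct IMUs")
    return MeasurementEvent(
        kind="JOINT_CENTER",
        imu_indices=(imu1, imu2),
        z=np.zeros(3),
        C=noise.sigma_jc**2 * np.eye(3),
        payload=(np.asarray(r1, dtype=float), np.asarray(r2, dtype=float)),
    )


def make_joint_axis(
    imu1: int, imu2: int, e1: np.ndarray, e2: np.ndarray, sigma_ja: float
) -> MeasurementEvent:
    """Soft-hinge axis-alignment pseudo-measurement (knee/hip; never ankle)."""
    if imu1 == imu2:
        raise ValueError("joint axis requires two distinct IMUs")
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    for e in (e1, e2):
        if abs(np.linalg.norm(e) - 1.0) > 1e-6:
            raise ValueError("joint axis vectors must be unit length")
    return MeasurementEvent(
        kind="JOINT_AXIS",
        imu_indices=(imu1, imu2),
        z=np.zeros(3),
        C=sigma_ja**2 * np.eye(3),
        payload=(e1, e2),
    )


def batch_update(
    x: NominalState, P: np.ndarray, events: Sequence[MeasurementEvent]
) -> tuple[NominalState, np.ndarray, dict]:
    """Apply all same-timestep measurements simultaneously.

    Stacks every event into one (3m × 9n) H, computes the Kalman gain with
    a symmetric (Cholesky) solve, injects the error mean into the nominal
    state (quaternion via the exponential map), resets the error mean and
    maps the covariance through the reset Jacobian G.
    """
    if len(events) == 0:
        raise ValueError("batch_update requires at least one event; use the "
                         "pass-through path when no measurements are observed")
    n = x.n_imus
    H = np.vstack([ev.jacobian(x) for ev in events])
    nu = np.concatenate([ev.innovation(x) for ev in events])
    m = H.shape[0]
    C = np.zeros((m, m))
    for i, ev in enumerate(events):
        C[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = ev.C

    PHt = P @ H.T
    S = H @ PHt + C
    S = 0.5 * (S + S.T)
    info: dict = {}
    try:
        cf = cho_factor(S, lower=True)
    except np.linalg.LinAlgError:
        S = S + 1e-12 * np.eye(m)
        cf = cho_factor(S, lower=True)
        info["jitter"] = 1e-12
        info["condition_number"] = float(np.linalg.cond(S))
    K = cho_solve(cf, PHt.T).T  # K = P Hᵀ S⁻¹
    dx = K @ nu

    x_new = x.copy()
    for j in range(n):
        b = 9 * j
        x_new.p[j] += dx[b : b + 3]
        x_new.v[j] += dx[b + 3 : b + 6]
        x_new.q[j] = quat_multiply(x.q[j], rotvec_to_quat(dx[b + 6 : b + 9]))

    IKH = np.eye(9 * n) - K @ H
    P_new = IKH @ P
    # reset Jacobian G: identity except attitude blocks I − [½δθ]ₓ
    G = np.eye(9 * n)
    for j in range(n):
        b = 9 * j
        G[b + 6 : b + 9, b + 6 : b + 9] = np.eye(3) - skew(0.5 * dx[b + 6 : b + 9])
    P_new = G @ P_new @ G.T
    P_new = 0.5 * (P_new + P_new.T)
    info["dx"] = dx
    return x_new, P_new, info


def initial_covariance(noise: NoiseConfig, n_imus: int) -> np.ndarray:
    d = np.concatenate(
        [
            np.full(3, noise.sigma_p0**2),
            np.full(3, noise.sigma_v0**2),
            np.full(3, noise.sigma_th0**2),
        ]
    )
    return np.diag(np.tile(d, n_imus))


@dataclass
class JointSpec:
    """A joint linking two IMUs, with its calibration vectors in IMU frames.

    ``sigma_ja`` is the joint-axis (soft hinge) noise in radians, or ``None``
    for joints without an axis correction (the ankles).
    """

    name: str
    imu1: int
    imu2: int
    r1: np.ndarray
    r2: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    sigma_ja: float | None = None


@dataclass
class CorrectionToggles:
    zupt: bool = True
    tilt: bool = True
    joint_center: bool = True
    joint_axis: bool = True

    @classmethod
    def none(cls) -> "CorrectionToggles":
        return cls(False, False, False, False)


@dataclass
class FilterResult:
    """Pose trajectory and bookkeeping from :func:`run_filter`."""

    t: np.ndarray  # (N,)
    p: np.ndarray  # (N, n, 3)
    v: np.ndarray  # (N, n, 3)
    q: np.ndarray  # (N, n, 4)
    event_counts: dict
    suppressed_tilts: int


def run_filter(
    acc: np.ndarray,
    gyr: np.ndarray,
    dt: float,
    x0: NominalState,
    P0: np.ndarray | None,
    noise: NoiseConfig,
    joints: Sequence[JointSpec] = (),
    still_mask: np.ndarray | None = None,
    footfalls: dict[int, np.ndarray] | None = None,
    toggles: CorrectionToggles | None = None,
) -> FilterResult:
    """Run the full predict/update loop over an IMU recording.

    Parameters
    ----------
    acc, gyr : (N, n, 3) arrays of specific force (m/s²) and angular
        velocity (rad/s) per sample and IMU.
    still_mask : (N, n) boolean — tilt corrections are attempted at every
        flagged sample (and suppressed when ‖a‖ is outside the gravity band).
    footfalls : mapping IMU index → sorted sample indices receiving a ZUPT.
    toggles : enables/disables each of the four corrections; with all four
        disabled the loop reduces exactly to strapdown integration.
    """
    acc = np.asarray(acc, dtype=float)
    gyr = np.asarray(gyr, dtype=float)
    N, n = acc.shape[0], acc.shape[1]
    if x0.n_imus != n:
        raise ValueError("initial state does not match number of IMUs")
    toggles = toggles if toggles is not None else CorrectionToggles()
    P = P0.copy() if P0 is not None else initial_covariance(noise, n)
    x = x0.copy()

    zupt_steps: dict[int, set] = {}
    if footfalls:
        for j, idx in footfalls.items():
            zupt_steps[j] = set(int(i) for i in np.asarray(idx).ravel())

    any_correction = (
        toggles.zupt or toggles.tilt or toggles.joint_center or toggles.joint_axis
    )

    out_p = np.empty((N, n, 3))
    out_v = np.empty((N, n, 3))
    out_q = np.empty((N, n, 4))
    counts = {"ZUPT": 0, "TILT": 0, "JOINT_CENTER": 0, "JOINT_AXIS": 0}
    suppressed = 0

    for k in range(N):
        if k > 0:
            x_pred = predict_state(x, acc[k - 1], gyr[k - 1], dt, noise)
            if any_correction:
                Fx = process_jacobian(x, acc[k - 1], gyr[k - 1], dt)
                P = predict_covariance(P, Fx, noise, dt)
            x = x_pred

        if any_correction:
            events: list[MeasurementEvent] = []
            if toggles.joint_center:
                for js in joints:
                    events.append(make_joint_center(js.imu1, js.imu2, js.r1, js.r2, noise))
            if toggles.joint_axis:
                for js in joints:
                    if js.sigma_ja is not None:
                        events.append(
                            make_joint_axis(js.imu1, js.imu2, js.e1, js.e2, js.sigma_ja)
                        )
            if toggles.zupt:
                for j, steps in zupt_steps.items():
                    if k in steps:
                        events.append(make_zupt(j, noise))
            if toggles.tilt and still_mask is not None:
                for j in np.nonzero(still_mask[k])[0]:
                    ev = make_tilt(int(j), acc[k, j], noise)
                    if ev is None:
                        suppressed += 1
                    else:
                        events.append(ev)
            if events:
                x, P, _ = batch_update(x, P, events)
                for ev in events:
                    counts[ev.kind] += 1
            # else: pass-through (x, P unchanged beyond prediction)

        if not (
            np.all(np.isfinite(x.p)) and np.all(np.isfinite(x.v)) and np.all(np.isfinite(x.q))
        ):
            last_good = NominalState(out_p[k - 1], out_v[k - 1], out_q[k - 1]) if k else x0
            raise FilterDivergence(k, last_good)
        out_p[k] = x.p
        out_v[k] = x.v
        out_q[k] = x.q

    t = np.arange(N) * dt
    return FilterResult(t, out_p, out_v, out_q, counts, suppressed)
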