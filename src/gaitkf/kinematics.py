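"""Segment orientations, joint angles, and spatiotemporal stride metrics.

Joint angles follow the joint-coordinate-system convention used in lower-limb
biomechanics: the relative rotation from the proximal to the distal anatomical
frame is decomposed in the body-fixed Z-X-Y sequence — flexion/extension about
the proximal medial-lateral (z) axis, internal/external rotation about the
distal longitudinal (y) axis, and abduction/adduction about the floating x
axis.  Left-side AbAd and IE are sign-flipped so that positive means
adduction/internal rotation on both sides.  The ankle is decomposed with the
same machinery; its three angles are conventionally labelled
dorsiflexion/plantarflexion (DP), internal/external rotation (IE) and
inversion/eversion (InEv).

Stride length is the horizontal (world xy) displacement of the heel between
consecutive same-foot footfalls; step width is the orthogonal distance of the
intermediate opposite-foot heel point from the supporting line of that stride
vector.  The first stride and last two strides of a trial are transition
strides and excluded from summary statistics.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .so3 import quat_to_matrix

__all__ = [
    "segment_orientation",
    "joint_angles",
    "joint_angle_series",
    "compose_joint_angles",
    "lowpass_zero_lag",
    "range_of_motion",
    "rom_summary",
    "heel_trajectory",
    "stride_metrics",
    "JOINTS",
    "ANGLE_LABELS",
]

log = logging.getLogger(__name__)

#: canonical joint order: (name, proximal segment, distal segment, side)
JOINTS = [
    ("hip_l", "pelvis", "thigh_l", "L"),
    ("hip_r", "pelvis", "thigh_r", "R"),
    ("knee_l", "thigh_l", "shank_l", "L"),
    ("knee_r", "thigh_r", "shank_r", "R"),
    ("ankle_l", "shank_l", "foot_l", "L"),
    ("ankle_r", "shank_r", "foot_r", "R"),
]

#: presentation labels per joint type (internal order is always Z, X, Y)
ANGLE_LABELS = {
    "hip": ("FE", "AbAd", "IE"),
    "knee": ("FE", "AbAd", "IE"),
    "ankle": ("DP", "InEv", "IE"),
}

_GIMBAL_TOL = 1e-6


def _check_rotation(R: np.ndarray, name: str, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"{name} must be 3×3")
    if np.linalg.norm(R.T @ R - np.eye(3)) > tol or np.linalg.det(R) < 0:
        raise ValueError(f"{name} is not a proper rotation matrix")
    return R


def segment_orientation(q_imu: np.ndarray, R_AS: np.ndarray) -> np.ndarray:
    """World-from-anatomical rotation of a segment.

    ``R_WA = R_WS · R_AS`` where ``R_WS`` is the IMU orientation and
    ``R_AS`` maps anatomical-frame coordinates to sensor-frame coordinates
    (y_W = R_WS y_S = R_WS R_AS y_A).
    """
    R_AS = _check_rotation(R_AS, "R_AS")
    return quat_to_matrix(q_imu) @ R_AS


def joint_angles(
    R_proximal: np.ndarray, R_distal: np.ndarray, side: str = "R"
) -> tuple[float, float, float]:
    """Decompose R_proxᵀ·R_dist in the intrinsic Z-X-Y sequence, degrees.

    Returns (flexion, adduction, internal-rotation); for ``side='L'`` the
    last two are sign-flipped so positive is adduction/internal on both
    sides.  Near gimbal lock (|cos x-angle| < 1e-6) all three are NaN.
    """
    Rp = _check_rotation(R_proximal, "R_proximal")
    Rd = _check_rotation(R_distal, "R_distal")
    R = Rp.T @ Rd
    # R = Rz(α) Rx(β) Ry(γ):  R[2,1] = sinβ,  R[0,1] = −sinα cosβ,
    # R[1,1] = cosα cosβ,  R[2,0] = −cosβ sinγ,  R[2,2] = cosβ cosγ
    sb = np.clip(R[2, 1], -1.0, 1.0)
    cb = np.sqrt(max(0.0, 1.0 - sb * sb))
    if cb < _GIMBAL_TOL:
        warnings.warn("gimbal proximity in joint angle decomposition", RuntimeWarning)
        return (np.nan, np.nan, np.nan)
    alpha = np.arctan2(-R[0, 1], R[1, 1])
    beta = np.arcsin(sb)
    gamma = np.arctan2(-R[2, 0], R[2, 2])
    sgn = -1.0 if side.upper().startswith("L") else 1.0
    return (
        float(np.degrees(alpha)),
        float(sgn * np.degrees(beta)),
        float(sgn * np.degrees(gamma)),
    )


def compose_joint_angles(
    fe: float, abad: float, ie: float, side: str = "R"
) -> np.ndarray:
    """Inverse of :func:`joint_angles`: build R_rel from a (deg) triple."""
    sgn = -1.0 if side.upper().startswith("L") else 1.0
    return Rotation.from_euler(
        "ZXY", [fe, sgn * abad, sgn * ie], degrees=True
    ).as_matrix()


def joint_angle_series(
    q_prox: np.ndarray,
    q_dist: np.ndarray,
    R_AS_prox: np.ndarray,
    R_AS_dist: np.ndarray,
    side: str = "R",
) -> np.ndarray:
    """(N, 3) joint-angle time series in degrees from two IMU quaternion
    streams and their sensor-to-segment rotations (vectorized)."""
    R_AS_prox = _check_rotation(R_AS_prox, "R_AS_prox")
    R_AS_dist = _check_rotation(R_AS_dist, "R_AS_dist")
    # scipy quats are xyzw
    Rp = Rotation.from_quat(np.roll(np.atleast_2d(q_prox), -1, axis=1)).as_matrix() @ R_AS_prox
    Rd = Rotation.from_quat(np.roll(np.atleast_2d(q_dist), -1, axis=1)).as_matrix() @ R_AS_dist
    R = np.einsum("nji,njk->nik", Rp, Rd)
    sb = np.clip(R[:, 2, 1], -1.0, 1.0)
    cb = np.sqrt(np.clip(1.0 - sb * sb, 0.0, None))
    alpha = np.arctan2(-R[:, 0, 1], R[:, 1, 1])
    beta = np.arcsin(sb)
    gamma = np.arctan2(-R[:, 2, 0], R[:, 2, 2])
    out = np.degrees(np.column_stack([alpha, beta, gamma]))
    out[cb < _GIMBAL_TOL] = np.nan
    if side.upper().startswith("L"):
        out[:, 1:] *= -1.0
    return out


def lowpass_zero_lag(
    series: np.ndarray,
    fc: float = 6.0,
    fs: float = 128.0,
    order: int = 4,
    min_segment: float = 0.2,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass, applied per contiguous segment.

    The filter is designed at ``order`` and run forward-backward; the design
    cutoff is pre-warped by (√2 − 1)^(−1/(2·order)) so the bidirectional
    −3 dB point sits at ``fc``.  NaN gaps split the series into segments;
    segments too short for the filter warm-up are left as NaN and logged.
    """
    if fs <= 2.0 * fc:
        raise ValueError("sampling rate must exceed twice the cutoff")
    series = np.asarray(series, dtype=float)
    out = np.full_like(series, np.nan)
    correction = (np.sqrt(2.0) - 1.0) ** (-1.0 / (2.0 * order))
    b, a = butter(order, fc * correction / (fs / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    min_len = max(int(np.ceil(min_segment * fs)), padlen + 1)

    finite = np.isfinite(series if series.ndim == 1 else series.sum(axis=-1))
    edges = np.flatnonzero(np.diff(finite.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [finite.size]))
    for s, e in zip(starts, ends):
        if not finite[s]:
            continue
        if e - s < min_len:
            log.info("dropping segment [%d, %d): too short to filter", s, e)
            continue
        out[s:e] = filtfilt(b, a, series[s:e], axis=0)
    return out


def range_of_motion(
    angles: np.ndarray, footfalls: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stride range of motion (max − min) of one angle series.

    Strides run between successive footfalls.  A stride containing any NaN
    sample is marked invalid (its ROM is NaN).  Returns ``(rom, valid)``;
    both empty when fewer than two footfalls exist.
    """
    angles = np.asarray(angles, dtype=float)
    footfalls = np.asarray(footfalls, dtype=int)
    if footfalls.size < 2:
        return np.empty(0), np.empty(0, dtype=bool)
    rom = np.full(footfalls.size - 1, np.nan)
    valid = np.zeros(footfalls.size - 1, dtype=bool)
    for i in range(footfalls.size - 1):
        seg = angles[footfalls[i] : footfalls[i + 1] + 1]
        if seg.size and np.all(np.isfinite(seg)):
            rom[i] = float(seg.max() - seg.min())
            valid[i] = True
    return rom, valid


def rom_summary(rom: np.ndarray, valid: np.ndarray, max_invalid_frac: float = 0.3):
    """Trial-level mean ROM, or None when more than 30 % of strides are
    invalid (summary suppressed)."""
    if valid.size == 0:
        return None
    if (1.0 - valid.mean()) > max_invalid_frac:
        return None
    return float(np.nanmean(rom[valid]))


def heel_trajectory(
    p: np.ndarray, q: np.ndarray, heel_offset: np.ndarray
) -> np.ndarray:
    """World heel path from a foot-IMU pose stream: p(t) + R(t)·offset."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    offset = np.asarray(heel_offset, dtype=float)
    R = Rotation.from_quat(np.roll(q, -1, axis=1)).as_matrix()
    return p + R @ offset


def _perp_distance_xy(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Distance of point c from the supporting line through a, b (xy plane)."""
    d = b[:2] - a[:2]
    n = np.linalg.norm(d)
    if n < 1e-12:
        return np.nan
    return float(abs(d[0] * (c[1] - a[1]) - d[1] * (c[0] - a[0])) / n)


def stride_metrics(
    heel_l: np.ndarray,
    heel_r: np.ndarray,
    footfalls_l: np.ndarray,
    footfalls_r: np.ndarray,
    fs: float = 128.0,
) -> pd.DataFrame:
    """Per-stride stride length and step width from heel paths.

    One row per stride (consecutive same-foot footfall pair).  ``SL`` is
    the horizontal heel displacement; ``SW`` the orthogonal distance of the
    intermediate opposite-foot heel point from the stride's supporting line
    (NaN, logged, when no intermediate opposite footfall exists).  The
    ``transition`` column flags each foot's first stride and last two
    strides, which are excluded from any trial summary.
    """
    heel = {"L": np.asarray(heel_l, dtype=float), "R": np.asarray(heel_r, dtype=float)}
    ff = {"L": np.asarray(footfalls_l, dtype=int), "R": np.asarray(footfalls_r, dtype=int)}
    rows = []
    for foot in ("L", "R"):
        other = "R" if foot == "L" else "L"
        f = ff[foot]
        n_strides = f.size - 1
        for i in range(n_strides):
            k0, k1 = f[i], f[i + 1]
            a = heel[foot][k0]
            b = heel[foot][k1]
            sl = float(np.linalg.norm((b - a)[:2]))
            mid = ff[other][(ff[other] > k0) & (ff[other] < k1)]
            if mid.size == 0:
                log.info("no intermediate %s footfall in stride [%d, %d)", other, k0, k1)
                sw = np.nan
            else:
                # with clean detection there is exactly one; otherwise take
                # the one nearest the stride's temporal midpoint
                k_mid = mid[np.argmin(np.abs(mid - 0.5 * (k0 + k1)))]
                sw = _perp_distance_xy(a, b, heel[other][k_mid])
            rows.append(
                {
                    "foot": foot,
                    "start_index": int(k0),
                    "end_index": int(k1),
                    "t_start": k0 / fs,
                    "t_end": k1 / fs,
                    "SL": sl,
                    "SW": sw,
                    "transition": i == 0 or i >= n_strides - 2,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "foot",
            "start_index",
            "end_index",
            "t_start",
            "t_end",
            "SL",
            "SW",
            "transition",
        ],
    )
    return df.sort_values(["t_start", "foot"]).reset_index(drop=True)
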