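"""Quaternion and SO(3) primitives.

Conventions used throughout the package:

* Quaternions are stored ``(w, x, y, z)`` (Hamiltonian convention) and rotate
  sensor-frame vectors into the world frame: ``[0, y_w] = q ⊗ [0, y_b] ⊗ q*``.
* Rotation vectors are axis·angle, in radians.
* Attitude perturbations are local (right-multiplicative): ``q ← q ⊗ δq``.

Every function that returns a unit quaternion renormalizes it, so norm drift
from repeated multiplication stays below 1e-9.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_identity",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "quat_to_matrix",
    "matrix_to_quat",
    "rotvec_to_quat",
    "quat_to_rotvec",
    "skew",
    "rodrigues",
    "normalize_quat",
]

_EPS = 1e-12


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values: {x!r}")
    return x


def quat_identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def normalize_quat(q: np.ndarray) -> np.ndarray:
    q = _check_finite(q, "quaternion")
    n = np.sqrt(np.dot(q, q))
    if n < _EPS:
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamiltonian product a ⊗ b, renormalized."""
    a = _check_finite(a, "a")
    b = _check_finite(b, "b")
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    out = np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )
    return normalize_quat(out)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate a body-frame vector into the world frame.

    Vector part of ``q ⊗ [0, v] ⊗ q*``, expanded to avoid building the
    intermediate quaternions.
    """
    q = _check_finite(q, "q")
    v = _check_finite(v, "v")
    w = q[0]
    u = q[1:]
    # v' = v + 2w (u × v) + 2 u × (u × v)
    uv = np.cross(u, v)
    return v + 2.0 * w * uv + 2.0 * np.cross(u, uv)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3×3 rotation matrix R with R v_body = v_world."""
    w, x, y, z = normalize_quat(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quat_to_matrix` (Shepperd's method), w >= 0."""
    R = _check_finite(R, "R")
    tr = np.trace(R)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(R[i, i] - R[j, j] - R[k, k] + 1.0) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    if q[0] < 0:
        q = -q
    return normalize_quat(q)


def rotvec_to_quat(v: np.ndarray) -> np.ndarray:
    """Exponential map: axis·angle vector → unit quaternion.

    The zero-angle limit is handled with the series expansion of
    sin(φ/2)/φ so there is no division by zero.
    """
    v = _check_finite(v, "rotation vector")
    angle = np.sqrt(np.dot(v, v))
    half = 0.5 * angle
    if angle < 1e-8:
        # sin(φ/2)/φ = 1/2 − φ²/48 + O(φ⁴)
        k = 0.5 - angle * angle / 48.0
    else:
        k = np.sin(half) / angle
    q = np.concatenate(([np.cos(half)], k * v))
    return normalize_quat(q)


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    """Logarithm map: unit quaternion → axis·angle with magnitude in [0, π]."""
    q = normalize_quat(q)
    if q[0] < 0:
        q = -q
    sin_half = np.sqrt(np.dot(q[1:], q[1:]))
    if sin_half < 1e-8:
        # angle/sin(angle/2) ≈ 2 + angle²/12 for small angles
        return 2.0 * q[1:]
    angle = 2.0 * np.arctan2(sin_half, q[0])
    return q[1:] * (angle / sin_half)


def skew(y: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrix: skew(y) @ u == y × u."""
    y = _check_finite(y, "y")
    return np.array(
        [
            [0.0, -y[2], y[1]],
            [y[2], 0.0, -y[0]],
            [-y[1], y[0], 0.0],
        ]
    )


def rodrigues(w: np.ndarray) -> np.ndarray:
    """Rodrigues' rotation formula: rotation matrix of an axis·angle vector.

    ``I cosφ + sinφ [s]ₓ + s sᵀ (1 − cosφ)`` with ``w = φ s``; the φ → 0
    limit returns the identity analytically.
    """
    w = _check_finite(w, "w")
    phi = np.sqrt(np.dot(w, w))
    if phi < 1e-12:
        return np.eye(3) + skew(w)  # first-order; exact at w = 0
    s = w / phi
    K = skew(s)
    return np.eye(3) * np.cos(phi) + np.sin(phi) * K + np.outer(s, s) * (1.0 - np.cos(phi))
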