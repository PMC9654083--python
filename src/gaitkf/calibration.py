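"""Sensor-to-segment calibration: the fixed geometry the filter consumes.

A :class:`CalibrationSet` holds, per segment, the anatomical→sensor rotation
R_AS; per joint, the joint-center offsets (r) and flexion-axis unit vectors
(e) expressed in each adjacent IMU's sense frame; and per foot, the heel
offset in the foot-IMU frame.  These are inputs here — estimated upstream
from motion capture or a functional calibration — not outputs of the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .erkf import JointSpec, NoiseConfig

__all__ = [
    "CalibrationSet",
    "compose_RAS",
    "fit_rotation_by_angular_velocity",
    "validate_calibration",
]

SCHEMA_VERSION = 1


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix (polar decomposition via SVD)."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def _is_rotation(R: np.ndarray, tol: float = 1e-6) -> bool:
    R = np.asarray(R, dtype=float)
    return (
        R.shape == (3, 3)
        and bool(np.all(np.isfinite(R)))
        and np.linalg.norm(R.T @ R - np.eye(3)) <= tol
        and np.linalg.det(R) > 0
    )


@dataclass
class CalibrationSet:
    """Per-segment/per-joint alignment parameters, all in IMU sense frames.

    joints maps a joint name to a dict with keys ``parent``, ``child``
    (segment names), ``r_parent``, ``r_child`` (joint-center offsets, m),
    ``e_parent``, ``e_child`` (flexion-axis unit vectors).
    """

    R_AS: dict[str, np.ndarray]
    joints: dict[str, dict]
    heel_offsets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.R_AS = {k: np.asarray(v, dtype=float) for k, v in self.R_AS.items()}
        for j in self.joints.values():
            for key in ("r_parent", "r_child", "e_parent", "e_child"):
                j[key] = np.asarray(j[key], dtype=float)
        self.heel_offsets = {
            k: np.asarray(v, dtype=float) for k, v in self.heel_offsets.items()
        }

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": SCHEMA_VERSION,
            "segments": {k: np.asarray(v).tolist() for k, v in self.R_AS.items()},
            "joints": {
                name: {
                    "parent": j["parent"],
                    "child": j["child"],
                    "r_parent": j["r_parent"].tolist(),
                    "r_child": j["r_child"].tolist(),
                    "e_parent": j["e_parent"].tolist(),
                    "e_child": j["e_child"].tolist(),
                }
                for name, j in self.joints.items()
            },
            "heel_offsets": {k: v.tolist() for k, v in self.heel_offsets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationSet":
        missing = {"segments", "joints"} - set(d)
        if missing:
            raise KeyError(f"calibration file missing required keys: {sorted(missing)}")
        return cls(
            R_AS=d["segments"],
            joints={k: dict(v) for k, v in d["joints"].items()},
            heel_offsets=d.get("heel_offsets", {}),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- filter plumbing ----------------------------------------------------

    def joint_specs(self, imu_order: list[str], noise: NoiseConfig) -> list[JointSpec]:
        """JointSpec list for :func:`gaitkf.erkf.run_filter`.

        The soft-hinge noise is selected by joint type: knee uses the tight
        knee value, hip the loose hip value, and the ankle gets no joint-axis
        correction at all.
        """
        index = {name: i for i, name in enumerate(imu_order)}
        specs = []
        for name, j in self.joints.items():
            if name.startswith("knee"):
                sigma = noise.sigma_ja_knee
            elif name.startswith("hip"):
                sigma = noise.sigma_ja_hip
            else:
                sigma = None
            specs.append(
                JointSpec(
                    name=name,
                    imu1=index[j["parent"]],
                    imu2=index[j["child"]],
                    r1=j["r_parent"],
                    r2=j["r_child"],
                    e1=j["e_parent"],
                    e2=j["e_child"],
                    sigma_ja=sigma,
                )
            )
        return specs


def compose_RAS(R_CS: np.ndarray, R_AC: np.ndarray) -> np.ndarray:
    """Anatomical→sensor rotation from cluster→sensor and anatomical→cluster.

    The matrix product R_CS·R_AC, re-orthonormalized through the polar
    decomposition when numerical drift has accumulated.
    """
    for name, R in (("R_CS", R_CS), ("R_AC", R_AC)):
        if not _is_rotation(np.asarray(R, dtype=float), tol=1e-4):
            raise ValueError(f"{name} is not a valid rotation matrix")
    out = np.asarray(R_CS, dtype=float) @ np.asarray(R_AC, dtype=float)
    if not _is_rotation(out, tol=1e-9):
        out = _orthonormalize(out)
    return out


def fit_rotation_by_angular_velocity(
    w_sensor: np.ndarray, w_reference: np.ndarray
) -> np.ndarray:
    """Least-squares rotation aligning two angular-velocity streams.

    Solves min_R Σₖ ‖ω_ref,k − R ω_sens,k‖² over proper rotations (the
    orthogonal Procrustes problem, via SVD with the determinant constrained
    to +1).  Requires time-aligned streams with non-collinear angular
    velocities; used to recover the cluster→sensor mounting rotation from a
    functional calibration movement.
    """
    ws = np.atleast_2d(np.asarray(w_sensor, dtype=float))
    wr = np.atleast_2d(np.asarray(w_reference, dtype=float))
    if ws.shape != wr.shape or ws.shape[0] < 3:
        raise ValueError("streams must be equal-length with at least 3 samples")
    M = wr.T @ ws
    U, s, Vt = np.linalg.svd(M)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise ValueError("angular velocities are collinear; rotation under-determined")
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def validate_calibration(
    calib: CalibrationSet,
    static_pose: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    axis_tol_deg: float = 2.0,
    center_tol: float = 0.01,
) -> dict:
    """Structured consistency report for a calibration set.

    Checks rotation validity, unit axes, offset magnitudes; when a static
    pose (segment name → (p_imu, R_WS)) is supplied, additionally checks
    that each joint's two axis vectors map to nearly equal world vectors
    and that the joint-center residual is below ``center_tol`` meters.
    """
    checks: list[dict] = []

    def record(name: str, ok: bool, detail: str = "") -> None:
        checks.append({"check": name, "passed": bool(ok), "detail": detail})

    for seg, R in calib.R_AS.items():
        record(f"R_AS[{seg}] is a rotation", _is_rotation(R))
    for name, j in calib.joints.items():
        for key in ("e_parent", "e_child"):
            record(
                f"{name}.{key} unit norm",
                abs(np.linalg.norm(j[key]) - 1.0) < 1e-6,
                f"norm={np.linalg.norm(j[key]):.6f}",
            )
        for key in ("r_parent", "r_child"):
            record(
                f"{name}.{key} magnitude < 1 m",
                bool(np.all(np.isfinite(j[key]))) and np.linalg.norm(j[key]) < 1.0,
            )
    for foot, h in calib.heel_offsets.items():
        record(f"heel_offset[{foot}] magnitude < 1 m", np.linalg.norm(h) < 1.0)

    if static_pose is not None:
        for name, j in calib.joints.items():
            if j["parent"] not in static_pose or j["child"] not in static_pose:
                continue
            p1, R1 = static_pose[j["parent"]]
            p2, R2 = static_pose[j["child"]]
            w1 = R1 @ j["e_parent"]
            w2 = R2 @ j["e_child"]
            ang = np.degrees(np.arccos(np.clip(np.dot(w1, w2), -1.0, 1.0)))
            record(
                f"{name} world axis agreement",
                ang < axis_tol_deg,
                f"angle={ang:.3f} deg",
            )
            resid = np.linalg.norm(
                (np.asarray(p1) + R1 @ j["r_parent"]) - (np.asarray(p2) + R2 @ j["r_child"])
            )
            record(
                f"{name} joint-center static residual",
                resid < center_tol,
                f"residual={resid:.4f} m",
            )

    return {"passed": all(c["passed"] for c in checks), "checks": checks}
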