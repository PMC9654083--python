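"""Readers and writers for fixtures and pipeline outputs.

Formats are documented in FORMATS.md: plain CSV for IMU streams and derived
quantities (angles in degrees, distances in meters, times in seconds from
stream start), YAML for calibration and manifests, HDF5 for ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationSet
from .erkf import NominalState

__all__ = [
    "load_imu_csv",
    "load_fixture",
    "load_truth",
    "write_results",
    "export_events",
]

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


def load_imu_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read one per-IMU stream CSV → (t, acc, gyr)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed IMU CSV {path.name}: {exc}") from exc
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name} lacks required columns {missing}")
    if df[IMU_COLUMNS].isna().any().any():
        bad = int(df[IMU_COLUMNS].isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path.name}: non-numeric or missing value near line {bad}")
    arr = df[IMU_COLUMNS].to_numpy(dtype=float)
    return arr[:, 0], arr[:, 1:4], arr[:, 4:7]


def load_truth(path: str | Path) -> dict:
    """Read a ground-truth HDF5 file into plain arrays."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        for key in ("t", "p", "v", "q", "p_analytic"):
            out[key] = f[key][()]
        out["imu_order"] = f.attrs["imu_order"].split(",")
        out["joint_angles"] = {k: v[()] for k, v in f["joint_angles"].items()}
        out["footfalls"] = {k: v[()] for k, v in f["footfalls"].items()}
        out["heel"] = {k: v[()] for k, v in f["heel"].items()}
    return out


def load_fixture(path: str | Path) -> dict:
    """Load a simulator fixture directory.

    Returns a dict with stacked ``acc``/``gyr`` (N, n, 3) in the manifest's
    IMU order, ``t``, ``fs``, the calibration, the initial state (taken
    from the ground truth), and the truth arrays when present.
    """
    root = Path(path)
    manifest_path = root / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.yaml under {root}")
    manifest = yaml.safe_load(manifest_path.read_text())

    imu_files = sorted(root.glob("imu_*.csv"))
    if not imu_files:
        raise FileNotFoundError(f"no imu_*.csv files under {root}")
    # canonical ordering comes from the truth file when available, else name-sorted
    truth = load_truth(root / "truth.h5") if (root / "truth.h5").exists() else None
    if truth is not None:
        order = truth["imu_order"]
    else:
        order = [p.stem.removeprefix("imu_") for p in imu_files]

    t_ref = None
    accs, gyrs = [], []
    for seg in order:
        t, acc, gyr = load_imu_csv(root / f"imu_{seg}.csv")
        if t_ref is None:
            t_ref = t
        elif t.shape != t_ref.shape or not np.allclose(t, t_ref):
            raise ValueError(f"time base of imu_{seg}.csv differs from the others")
        accs.append(acc)
        gyrs.append(gyr)
    acc = np.stack(accs, axis=1)
    gyr = np.stack(gyrs, axis=1)
    fs = 1.0 / float(np.median(np.diff(t_ref)))

    calibration = CalibrationSet.from_yaml(root / "calibration.yaml")

    initial_state = None
    if truth is not None:
        initial_state = NominalState(truth["p"][0], truth["v"][0], truth["q"][0])

    return {
        "t": t_ref,
        "acc": acc,
        "gyr": gyr,
        "fs": fs,
        "imu_order": order,
        "calibration": calibration,
        "initial_state": initial_state,
        "truth": truth,
        "manifest": manifest,
    }


def export_events(
    still_intervals: dict[str, list[tuple[int, int]]],
    footfalls: dict[str, np.ndarray],
    path: str | Path,
) -> None:
    """Events CSV: imu_id, kind (STILL/FOOTFALL), start_index, end_index."""
    rows = []
    for seg, intervals in still_intervals.items():
        for s, e in intervals:
            rows.append({"imu_id": seg, "kind": "STILL", "start_index": s, "end_index": e})
    for seg, idx in footfalls.items():
        for k in np.asarray(idx).ravel():
            rows.append({"imu_id": seg, "kind": "FOOTFALL",
                         "start_index": int(k), "end_index": int(k)})
    pd.DataFrame(rows, columns=["imu_id", "kind", "start_index", "end_index"]).to_csv(
        path, index=False
    )


def write_results(results, out_dir: str | Path, summary_extra: dict | None = None) -> dict:
    """Write pose/angle/stride CSVs and a JSON summary for one fit.

    Returns the summary dict.  Angles are serialized in degrees under the
    canonical column triple (FE, AbAd, IE); for the ankle these carry DP
    and InEv (see FORMATS.md).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj = results.trajectory
    order = results.model.imu_order

    pose_rows = []
    for j, seg in enumerate(order):
        df = pd.DataFrame(
            {
                "t": traj.t,
                "imu_id": seg,
                "px": traj.p[:, j, 0], "py": traj.p[:, j, 1], "pz": traj.p[:, j, 2],
                "vx": traj.v[:, j, 0], "vy": traj.v[:, j, 1], "vz": traj.v[:, j, 2],
                "qw": traj.q[:, j, 0], "qx": traj.q[:, j, 1],
                "qy": traj.q[:, j, 2], "qz": traj.q[:, j, 3],
            }
        )
        pose_rows.append(df)
    pd.concat(pose_rows, ignore_index=True).to_csv(out / "poses.csv", index=False,
                                                   float_format="%.9g")

    angle_rows = []
    for joint in sorted({j for j, _ in results.joint_angles.columns}):
        sub = results.joint_angles[joint]
        df = pd.DataFrame({"t": results.joint_angles.index, "joint": joint})
        for k, col in enumerate(["FE", "AbAd", "IE"]):
            df[col] = sub.iloc[:, k].to_numpy()
        angle_rows.append(df)
    pd.concat(angle_rows, ignore_index=True).to_csv(out / "joint_angles.csv",
                                                    index=False, float_format="%.9g")

    strides = results.strides.copy()
    # attach ipsilateral per-stride ROM columns keyed by stride start index
    for (joint, lab), grp in results.rom.groupby(["joint", "angle"], sort=False):
        col = f"rom_{joint}_{lab}"
        mapping = dict(zip(grp["start_index"], grp["rom"]))
        foot = "L" if joint.endswith("_l") else "R"
        strides[col] = [
            mapping.get(si, np.nan) if f == foot else np.nan
            for si, f in zip(strides["start_index"], strides["foot"])
        ]
    strides.to_csv(out / "strides.csv", index=False, float_format="%.9g")

    heel_rows = []
    for seg, tr in results.heel.items():
        heel_rows.append(pd.DataFrame({"t": traj.t, "foot": seg,
                                       "x": tr[:, 0], "y": tr[:, 1], "z": tr[:, 2]}))
    if heel_rows:
        pd.concat(heel_rows, ignore_index=True).to_csv(out / "heel_trajectories.csv",
                                                       index=False, float_format="%.9g")

    export_events(results.still_intervals, results.footfalls, out / "events.csv")

    ok = strides[~strides["transition"]]
    summary = {
        "n_samples": int(traj.t.size),
        "fs": results.model.fs,
        "event_counts": {k: int(v) for k, v in traj.event_counts.items()},
        "suppressed_tilt_events": int(traj.suppressed_tilts),
        "footfall_counts": {k: int(v.size) for k, v in results.footfalls.items()},
        "n_strides": int(len(ok)),
        "mean_sl": float(ok["SL"].mean()) if len(ok) else None,
        "mean_sw": float(ok["SW"].mean()) if len(ok) else None,
        "corrections_enabled": {
            "zupt": results.model.toggles.zupt,
            "tilt": results.model.toggles.tilt,
            "joint_center": results.model.toggles.joint_center,
            "joint_axis": results.model.toggles.joint_axis,
        },
        "prediction_only": not any(
            [results.model.toggles.zupt, results.model.toggles.tilt,
             results.model.toggles.joint_center, results.model.toggles.joint_axis]
        ),
    }
    if summary_extra:
        summary.update(summary_extra)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
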