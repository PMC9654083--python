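"""Model/Results interface tying the full pipeline together.

:class:`GaitFilterModel` is built from a multi-IMU recording plus its
sensor-to-segment calibration and initial pose; ``fit()`` detects gait
events, runs the error-state Kalman filter, derives joint angles, heel
trajectories and stride metrics, and returns a :class:`GaitFilterResults`
carrying the estimates, diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as _events
from . import kinematics as _kin
from .calibration import CalibrationSet
from .erkf import (
    CorrectionToggles,
    FilterResult,
    NoiseConfig,
    NominalState,
    initial_covariance,
    run_filter,
)

__all__ = ["GaitFilterModel", "GaitFilterResults", "compare_strides"]


def _joint_side(joint: str) -> str:
    return "L" if joint.endswith("_l") else "R"


def _joint_type(joint: str) -> str:
    return joint.split("_")[0]


class GaitFilterModel:
    """Error-state Kalman filter model of a lower-limb IMU recording.

    Parameters
    ----------
    acc, gyr : (N, n, 3) specific force (m/s²) and angular rate (rad/s)
        streams, one column block per IMU in ``imu_order``.
    calibration : sensor-to-segment alignment (rotations, joint centers,
        axes, heel offsets) in IMU frames.
    initial_state : nominal pose of every IMU at the first sample.
    imu_order : segment names matching the stream columns; names starting
        with ``foot`` receive ZUPTs.
    noise, detection, toggles : filter noises, event-detection thresholds,
        and per-correction enable flags.

    Examples
    --------
    >>> from gaitkf.simulator import GaitSpec, generate_truth, synthesize_imu
    >>> truth = generate_truth(GaitSpec.preset("forward_normal", trial_duration=10.0))
    >>> acc, gyr = synthesize_imu(truth)
    >>> model = GaitFilterModel(acc, gyr, truth.calibration,
    ...                         truth.initial_state(), imu_order=truth.imu_order)
    >>> res = model.fit()
    >>> res.strides[["foot", "SL", "SW"]].head()  # doctest: +SKIP
    """

    def __init__(
        self,
        acc: np.ndarray,
        gyr: np.ndarray,
        calibration: CalibrationSet,
        initial_state: NominalState,
        imu_order: list[str],
        fs: float = 128.0,
        noise: NoiseConfig | None = None,
        detection: _events.DetectionConfig | None = None,
        toggles: CorrectionToggles | None = None,
        P0: np.ndarray | None = None,
        angle_cutoff_hz: float = 6.0,
    ):
        self.acc = np.asarray(acc, dtype=float)
        self.gyr = np.asarray(gyr, dtype=float)
        if self.acc.shape != self.gyr.shape or self.acc.ndim != 3:
            raise ValueError("acc and gyr must both be (N, n, 3)")
        if len(imu_order) != self.acc.shape[1]:
            raise ValueError("imu_order length does not match stream columns")
        self.calibration = calibration
        self.initial_state = initial_state
        self.imu_order = list(imu_order)
        self.fs = float(fs)
        self.noise = noise if noise is not None else NoiseConfig()
        self.detection = detection if detection is not None else _events.DetectionConfig()
        self.toggles = toggles if toggles is not None else CorrectionToggles()
        self.P0 = P0
        self.angle_cutoff_hz = float(angle_cutoff_hz)

    @classmethod
    def from_fixture(cls, path, **kwargs) -> "GaitFilterModel":
        """Build the model from a fixture directory written by the
        simulator (IMU CSVs + calibration.yaml + truth.h5 for the initial
        pose)."""
        from .io import load_fixture

        fx = load_fixture(path)
        kwargs.setdefault("fs", fx["fs"])
        return cls(
            fx["acc"], fx["gyr"], fx["calibration"], fx["initial_state"],
            imu_order=fx["imu_order"], **kwargs,
        )

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "GaitFilterResults":
        N, n = self.acc.shape[0], self.acc.shape[1]
        dt = 1.0 / self.fs

        still_intervals: dict[str, list[tuple[int, int]]] = {}
        mask = np.zeros((N, n), dtype=bool)
        footfalls: dict[int, np.ndarray] = {}
        footfalls_by_name: dict[str, np.ndarray] = {}
        for j, seg in enumerate(self.imu_order):
            intervals = _events.detect_still(self.gyr[:, j], self.fs, config=self.detection)
            still_intervals[seg] = intervals
            mask[:, j] = _events.tilt_eligible_mask(
                intervals, self.gyr[:, j], self.acc[:, j], config=self.detection
            )
            if seg.startswith("foot"):
                ff = _events.detect_footfalls(
                    intervals, self.gyr[:, j], self.acc[:, j], self.fs, config=self.detection
                )
                footfalls[j] = ff
                footfalls_by_name[seg] = ff

        joints = self.calibration.joint_specs(self.imu_order, self.noise)
        traj = run_filter(
            self.acc,
            self.gyr,
            dt,
            self.initial_state,
            self.P0,
            self.noise,
            joints=joints,
            still_mask=mask,
            footfalls=footfalls,
            toggles=self.toggles,
        )

        angles = self._joint_angle_frame(traj)
        heel = {}
        for seg in footfalls_by_name:
            j = self.imu_order.index(seg)
            heel[seg] = _kin.heel_trajectory(
                traj.p[:, j], traj.q[:, j], self.calibration.heel_offsets[seg]
            )
        strides, rom = self._stride_tables(angles, heel, footfalls_by_name)

        return GaitFilterResults(
            model=self,
            trajectory=traj,
            joint_angles=angles,
            heel=heel,
            still_intervals=still_intervals,
            footfalls=footfalls_by_name,
            strides=strides,
            rom=rom,
        )

    def _joint_angle_frame(self, traj: FilterResult) -> pd.DataFrame:
        idx = {name: i for i, name in enumerate(self.imu_order)}
        cols: dict[tuple[str, str], np.ndarray] = {}
        for joint, jdef in self.calibration.joints.items():
            side = _joint_side(joint)
            labels = _kin.ANGLE_LABELS.get(_joint_type(joint), ("FE", "AbAd", "IE"))
            series = _kin.joint_angle_series(
                traj.q[:, idx[jdef["parent"]]],
                traj.q[:, idx[jdef["child"]]],
                self.calibration.R_AS[jdef["parent"]],
                self.calibration.R_AS[jdef["child"]],
                side=side,
            )
            for k, lab in enumerate(labels):
                cols[(joint, lab)] = _kin.lowpass_zero_lag(
                    series[:, k], fc=self.angle_cutoff_hz, fs=self.fs
                )
        frame = pd.DataFrame(cols, index=traj.t)
        frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["joint", "angle"])
        frame.index.name = "t"
        return frame

    def _stride_tables(self, angles, heel, footfalls):
        if "foot_l" in heel and "foot_r" in heel:
            strides = _kin.stride_metrics(
                heel["foot_l"], heel["foot_r"],
                footfalls.get("foot_l", np.empty(0, int)),
                footfalls.get("foot_r", np.empty(0, int)),
                fs=self.fs,
            )
        else:
            strides = pd.DataFrame(
                columns=["foot", "start_index", "end_index", "t_start", "t_end",
                         "SL", "SW", "transition"]
            )
        rom_rows = []
        for joint in self.calibration.joints:
            side = _joint_side(joint)
            foot = "foot_l" if side == "L" else "foot_r"
            ff = footfalls.get(foot, np.empty(0, int))
            for (jt, lab) in angles.columns:
                if jt != joint:
                    continue
                rom, valid = _kin.range_of_motion(angles[(jt, lab)].to_numpy(), ff)
                for i, (r, ok) in enumerate(zip(rom, valid)):
                    rom_rows.append(
                        {"joint": joint, "angle": lab, "stride": i,
                         "start_index": int(ff[i]), "end_index": int(ff[i + 1]),
                         "rom": r, "valid": bool(ok)}
                    )
        rom = pd.DataFrame(
            rom_rows,
            columns=["joint", "angle", "stride", "start_index", "end_index", "rom", "valid"],
        )
        return strides, rom


@dataclass
class GaitFilterResults:
    """Estimates and diagnostics from one filtered trial."""

    model: GaitFilterModel
    trajectory: FilterResult
    joint_angles: pd.DataFrame  # index t, columns (joint, angle), degrees
    heel: dict[str, np.ndarray]
    still_intervals: dict[str, list[tuple[int, int]]]
    footfalls: dict[str, np.ndarray]
    strides: pd.DataFrame
    rom: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False)

    # -- derived summaries --------------------------------------------------

    def stride_summary(self) -> pd.DataFrame:
        """Mean/SD of SL and SW over non-transition strides."""
        ok = self.strides[~self.strides["transition"]]
        return ok[["SL", "SW"]].agg(["mean", "std", "count"])

    def rom_summary(self) -> pd.DataFrame:
        """Trial-mean ROM per joint angle; NaN when more than 30 % of the
        strides are invalid (summary suppressed)."""
        rows = []
        for (joint, lab), grp in self.rom.groupby(["joint", "angle"], sort=False):
            val = _kin.rom_summary(grp["rom"].to_numpy(), grp["valid"].to_numpy())
            rows.append({"joint": joint, "angle": lab,
                         "mean_rom": np.nan if val is None else val,
                         "n_strides": int(grp["valid"].sum())})
        return pd.DataFrame(rows)

    def angle_rms_error(self, truth_angles: dict[str, np.ndarray]) -> pd.DataFrame:
        """RMS error (deg) of each joint angle against ground-truth series
        keyed by joint name, arrays in (flexion, adduction, internal) order."""
        rows = []
        for joint, truth in truth_angles.items():
            labels = _kin.ANGLE_LABELS.get(_joint_type(joint), ("FE", "AbAd", "IE"))
            for k, lab in enumerate(labels):
                est = self.joint_angles[(joint, lab)].to_numpy()
                ref = np.asarray(truth)[: est.size, k]
                d = est - ref
                d = d[np.isfinite(d)]
                rows.append({"joint": joint, "angle": lab,
                             "rms_deg": float(np.sqrt(np.mean(d * d)))})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit report."""
        buf = _io.StringIO()
        n = len(self.model.imu_order)
        N = self.trajectory.t.size
        print("Lower-limb error-state Kalman filter results", file=buf)
        print("=" * 52, file=buf)
        print(f"IMUs: {n} ({', '.join(self.model.imu_order)})", file=buf)
        print(f"Samples: {N} at {self.model.fs:g} Hz "
              f"({N / self.model.fs:.1f} s)", file=buf)
        cnt = self.trajectory.event_counts
        print("Measurement corrections applied:", file=buf)
        for kind in ("ZUPT", "TILT", "JOINT_CENTER", "JOINT_AXIS"):
            print(f"  {kind:<13s} {cnt.get(kind, 0):8d}", file=buf)
        print(f"  suppressed tilt events: {self.trajectory.suppressed_tilts}", file=buf)
        for seg, ff in self.footfalls.items():
            print(f"Footfalls ({seg}): {ff.size}", file=buf)
        ok = self.strides[~self.strides["transition"]]
        if len(ok):
            print(f"Strides (non-transition): {len(ok)}", file=buf)
            print(f"  stride length  {ok['SL'].mean():.3f} ± {ok['SL'].std():.3f} m",
                  file=buf)
            print(f"  step width     {ok['SW'].mean():.3f} ± {ok['SW'].std():.3f} m",
                  file=buf)
        rs = self.rom_summary()
        if len(rs):
            print("Mean range of motion per joint angle (deg):", file=buf)
            for _, r in rs.iterrows():
                val = "suppressed" if np.isnan(r["mean_rom"]) else f"{r['mean_rom']:6.1f}"
                print(f"  {r['joint']:<9s} {r['angle']:<5s} {val}", file=buf)
        return buf.getvalue()

    def plot_joint_angles(self, joints=None, ax=None):
        """Joint-angle time series plot (matplotlib)."""
        import matplotlib.pyplot as plt

        joints = joints or sorted({j for j, _ in self.joint_angles.columns})
        fig, axes = plt.subplots(len(joints), 1, sharex=True,
                                 figsize=(8, 2.2 * len(joints)), squeeze=False)
        for axi, joint in zip(axes[:, 0], joints):
            sub = self.joint_angles[joint]
            for col in sub.columns:
                axi.plot(sub.index, sub[col], label=col)
            axi.set_ylabel(f"{joint} (deg)")
            axi.legend(loc="upper right", fontsize="small")
        axes[-1, 0].set_xlabel("time (s)")
        fig.tight_layout()
        return fig


def compare_strides(est: pd.DataFrame, ref: pd.DataFrame) -> dict:
    """RMS differences in SL and SW between two stride tables sharing the
    same footfall indices (non-transition strides only)."""
    key = ["foot", "start_index", "end_index"]
    a = est[~est["transition"]].set_index(key)
    b = ref[~ref["transition"]].set_index(key)
    joined = a[["SL", "SW"]].join(b[["SL", "SW"]], lsuffix="_est", rsuffix="_ref",
                                  how="inner")
    out = {}
    for m in ("SL", "SW"):
        d = (joined[f"{m}_est"] - joined[f"{m}_ref"]).to_numpy()
        d = d[np.isfinite(d)]
        out[f"{m.lower()}_rms"] = float(np.sqrt(np.mean(d * d))) if d.size else np.nan
        out[f"n_{m.lower()}"] = int(d.size)
    return out
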