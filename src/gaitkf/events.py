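"""Still-period and footfall detection from raw IMU signals.

Still periods are maximal runs where the gyroscope magnitude stays below a
threshold (default 60 deg/s) for at least ``min_duration``.  Footfalls — the
single near-still instant per stance at which a ZUPT is applied — are picked
inside each sufficiently long still interval of a foot IMU as the sample
minimizing an energy score combining angular rate and the deviation of the
accelerometer magnitude from gravity.  Both detectors use only vector norms,
so they are invariant to any fixed rotation of the sensor frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DetectionConfig", "detect_still", "detect_footfalls", "still_mask"]

GRAVITY_MAG = 9.81


@dataclass
class DetectionConfig:
    """Thresholds for still/footfall detection.

    still_threshold : rad/s, gyro-magnitude bound for stillness (60 deg/s).
    min_duration : s, shortest run counted as a still period.
    min_stance : s, shortest still interval eligible for a footfall.
    accel_weight : weight of |‖a‖ − g| (m/s²) against ‖ω‖ (rad/s) in the
        footfall energy score.
    max_footfall_score : stillness gate — an interval yields a footfall
        only if its best energy score falls below this value.  A truly
        planted foot scores near zero (gyro noise level); slowly rotating
        but translating swing-phase windows score well above it.
    max_tilt_score : per-sample stillness gate for gravitational tilt
        corrections inside detected still intervals.  The 60 deg/s gyro
        threshold alone flags segments that rotate slowly while still
        accelerating (pelvis sway, early/late stance), whose accelerometer
        direction is a poor gravity estimate; the score gate keeps tilt
        corrections to samples that are quasi-static in both channels.
    """

    still_threshold: float = float(np.deg2rad(60.0))
    min_duration: float = 0.05
    min_stance: float = 0.1
    accel_weight: float = 1.0
    max_footfall_score: float = 0.3
    max_tilt_score: float = 0.3


def detect_still(
    gyr: np.ndarray,
    fs: float,
    threshold: float | None = None,
    min_duration: float | None = None,
    config: DetectionConfig | None = None,
) -> list[tuple[int, int]]:
    """Maximal half-open index intervals with ‖ω‖ < threshold.

    Returns a sorted, non-overlapping list of ``(start, end)`` pairs;
    intervals shorter than ``min_duration`` seconds are dropped.
    """
    cfg = config or DetectionConfig()
    threshold = cfg.still_threshold if threshold is None else threshold
    min_duration = cfg.min_duration if min_duration is None else min_duration
    gyr = np.asarray(gyr, dtype=float)
    if gyr.size == 0:
        return []
    mag = np.linalg.norm(gyr, axis=-1)
    below = mag < threshold
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [below.size]))
    min_len = int(np.ceil(min_duration * fs))
    return [
        (int(s), int(e))
        for s, e in zip(starts, ends)
        if below[s] and (e - s) >= max(min_len, 1)
    ]


def detect_footfalls(
    still: list[tuple[int, int]],
    gyr: np.ndarray,
    acc: np.ndarray,
    fs: float,
    config: DetectionConfig | None = None,
) -> np.ndarray:
    """One footfall index per qualifying still interval of a foot IMU.

    Within each interval of at least ``min_stance`` seconds, the footfall is
    the sample minimizing ``‖ω‖ + accel_weight·|‖a‖ − g|`` (earliest index on
    ties); intervals whose best score exceeds ``max_footfall_score`` are not
    true stance dwells (e.g. slow-rotation swing windows) and yield no
    footfall.  Returns a strictly increasing integer array.
    """
    cfg = config or DetectionConfig()
    gyr = np.asarray(gyr, dtype=float)
    acc = np.asarray(acc, dtype=float)
    w_mag = np.linalg.norm(gyr, axis=-1)
    a_dev = np.abs(np.linalg.norm(acc, axis=-1) - GRAVITY_MAG)
    score = w_mag + cfg.accel_weight * a_dev
    min_len = int(np.ceil(cfg.min_stance * fs))
    out = []
    for s, e in still:
        if e - s < max(min_len, 1):
            continue
        k = s + int(np.argmin(score[s:e]))  # argmin takes first on ties
        if score[k] <= cfg.max_footfall_score:
            out.append(k)
    return np.asarray(out, dtype=int)


def still_mask(still: list[tuple[int, int]], n_samples: int) -> np.ndarray:
    """Boolean per-sample mask from a list of half-open intervals."""
    mask = np.zeros(n_samples, dtype=bool)
    for s, e in still:
        mask[s:e] = True
    return mask


def tilt_eligible_mask(
    still: list[tuple[int, int]],
    gyr: np.ndarray,
    acc: np.ndarray,
    config: DetectionConfig | None = None,
) -> np.ndarray:
    """Samples eligible for a gravitational tilt correction.

    Inside detected still intervals, a sample qualifies when its stillness
    energy score ``‖ω‖ + accel_weight·|‖a‖ − g|`` is below
    ``max_tilt_score`` — i.e. the IMU is quasi-static, not merely rotating
    slowly while accelerating.
    """
    cfg = config or DetectionConfig()
    gyr = np.asarray(gyr, dtype=float)
    acc = np.asarray(acc, dtype=float)
    score = np.linalg.norm(gyr, axis=-1) + cfg.accel_weight * np.abs(
        np.linalg.norm(acc, axis=-1) - GRAVITY_MAG
    )
    mask = still_mask(still, score.shape[0])
    return mask & (score < cfg.max_tilt_score)
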