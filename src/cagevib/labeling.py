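"""Camera-reference ground truth: head velocity from pose tracks and
threshold classification of 15-s windows into the three activity classes.

The head velocity is the per-frame minimum of the absolute frame-to-frame
speeds of the two ears and the headbase. Taking the minimum suppresses
spurious velocity spikes from single-point misdetections, at the cost of
underestimating rotational movements — a deliberate bias towards
underestimation. Window means below 1 px/s are resting, above 50 px/s
locomotion, and everything in the closed interval [1, 50] px/s stationary
activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from .imu import WINDOW_S
from .sim import POSE_POINTS, ActivityClass, PoseTrack

__all__ = [
    "LabelThresholds", "VelocitySeries", "LabeledWindow", "point_speeds",
    "head_velocity", "window_mean_velocity", "classify_velocity",
    "label_windows", "write_labels_csv", "read_labels_csv",
    "LIKELIHOOD_MIN", "MIN_COVERAGE",
]

#: A point detection below this likelihood is treated as invalid.
LIKELIHOOD_MIN = 0.9
#: A window with a smaller fraction of valid frames is marked invalid.
MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class LabelThresholds:
    """Velocity thresholds separating the classes, in px/s."""

    resting_max: float = 1.0
    locomotion_min: float = 50.0

    def __post_init__(self):
        if not 0 < self.resting_max < self.locomotion_min:
            raise ContractError("thresholds must satisfy 0 < resting_max < locomotion_min")


@dataclass
class VelocitySeries:
    """Per-frame head speed (px/s) with a validity flag per frame interval."""

    speeds: np.ndarray
    valid: np.ndarray
    fps: float

    def __len__(self) -> int:
        return len(self.speeds)


@dataclass(frozen=True)
class LabeledWindow:
    index: int
    start_time: float
    mean_velocity: float
    label: ActivityClass
    valid: bool = True


def point_speeds(track: PoseTrack,
                 likelihood_min: float = LIKELIHOOD_MIN) -> tuple[np.ndarray, np.ndarray]:
    """Absolute frame-to-frame speed of each tracked point.

    Returns ``(speeds, valid)``, both shaped (3, n_frames-1) in the point
    order right_ear / left_ear / headbase. ``speed[i] = |pos[i+1]−pos[i]|·fps``
    (2-D Euclidean, pixel space). A speed is valid only when both bounding
    detections meet the likelihood criterion. A track of fewer than two
    frames yields empty arrays.
    """
    n = track.n_frames
    if n < 2:
        return np.empty((3, 0)), np.empty((3, 0), dtype=bool)
    speeds = np.empty((3, n - 1))
    valid = np.empty((3, n - 1), dtype=bool)
    for k, name in enumerate(POSE_POINTS):
        pos = track.positions[name]
        speeds[k] = np.linalg.norm(np.diff(pos, axis=0), axis=1) * track.fps
        ok = track.likelihood[name] >= likelihood_min
        valid[k] = ok[:-1] & ok[1:]
    return speeds, valid


def head_velocity(speeds: np.ndarray, valid: np.ndarray | None = None,
                  fps: float = 30.0) -> VelocitySeries:
    """Per-frame head speed: the minimum over the valid point speeds.

    A frame interval is invalid when all three points are invalid; its speed
    is recorded as NaN.
    """
    speeds = np.asarray(speeds, dtype=float)
    if valid is None:
        valid = np.ones_like(speeds, dtype=bool)
    masked = np.where(valid, speeds, np.inf)
    out = masked.min(axis=0)
    any_valid = valid.any(axis=0)
    out[~any_valid] = np.nan
    return VelocitySeries(out, any_valid, fps)


def window_mean_velocity(series: VelocitySeries, window_s: float = WINDOW_S,
                         min_coverage: float = MIN_COVERAGE) -> tuple[np.ndarray, np.ndarray]:
    """Mean head speed of consecutive ``window_s`` windows.

    Returns ``(means, valid)``. The mean is taken over valid frame intervals
    only (450 of them per 15-s window at 30 fps); a window whose valid
    fraction falls below ``min_coverage`` is flagged invalid and its mean set
    to NaN.
    """
    per = int(round(window_s * series.fps))
    n_windows = len(series.speeds) // per
    means = np.full(n_windows, np.nan)
    ok = np.zeros(n_windows, dtype=bool)
    for i in range(n_windows):
        sl = slice(i * per, (i + 1) * per)
        v = series.valid[sl]
        if v.mean() >= min_coverage:
            means[i] = series.speeds[sl][v].mean()
            ok[i] = True
    return means, ok


def classify_velocity(mean_v: float, thresholds: LabelThresholds = LabelThresholds()) -> ActivityClass:
    """Classify a 15-s mean velocity: < 1 px/s resting, > 50 px/s locomotion,
    the closed interval [1, 50] px/s stationary activity (ties go to the
    middle class)."""
    if mean_v < 0 or np.isnan(mean_v):
        raise ContractError("mean velocity must be a non-negative number")
    if mean_v < thresholds.resting_max:
        return ActivityClass.RESTING
    if mean_v > thresholds.locomotion_min:
        return ActivityClass.LOCOMOTION
    return ActivityClass.STATIONARY


def label_windows(track: PoseTrack, window_s: float = WINDOW_S,
                  thresholds: LabelThresholds = LabelThresholds(),
                  start_time: float = 0.0,
                  likelihood_min: float = LIKELIHOOD_MIN,
                  min_coverage: float = MIN_COVERAGE) -> list[LabeledWindow]:
    """Full reference pipeline: point speeds → min-of-three → 15-s means → labels.

    Invalid windows are returned with ``valid=False`` and a NaN mean so the
    caller can drop them explicitly.
    """
    speeds, valid = point_speeds(track, likelihood_min)
    series = head_velocity(speeds, valid, track.fps)
    means, ok = window_mean_velocity(series, window_s, min_coverage)
    out = []
    for i, (m, v) in enumerate(zip(means, ok)):
        label = classify_velocity(float(m), thresholds) if v else ActivityClass.RESTING
        out.append(LabeledWindow(i, start_time + i * window_s, float(m), label, valid=bool(v)))
    return out


def write_labels_csv(labels: list[LabeledWindow], path) -> None:
    pd.DataFrame(
        {"window_index": [l.index for l in labels],
         "start_time": [l.start_time for l in labels],
         "mean_velocity": [l.mean_velocity for l in labels],
         "label": [l.label.value for l in labels],
         "valid": [l.valid for l in labels]}
    ).to_csv(path, index=False)


def read_labels_csv(path) -> list[LabeledWindow]:
    table = pd.read_csv(path)
    return [
        LabeledWindow(int(r["window_index"]), float(r["start_time"]),
                      float(r["mean_velocity"]), ActivityClass(r["label"]),
                      bool(r.get("valid", True)))
        for _, r in table.iterrows()
    ]
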