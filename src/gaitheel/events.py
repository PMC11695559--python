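"""Gait-event detection from heel keypoint trajectories.

Heel strikes are approximated by peaks in the absolute heel-to-heel image
distance: the moment a swinging foot lands is the moment the two heels are
farthest apart.  The distance series is lightly smoothed with a moving
average before peak picking; missing frames (confidence 0) are filled by
linear interpolation so single dropouts do not fragment the series.

Gait intervals (excluding sit-to-stand and turning) are found from the
smoothed forward heel velocity: sustained motion above a speed threshold for
a minimum duration is labelled gait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal

from .errors import EmptyOverlapError, SeriesTooShortError
from .geometry import ImagePoint
from .pose import PoseFrame

__all__ = [
    "Trajectory",
    "DistanceSeries",
    "heel_to_heel_distance",
    "detect_heel_strikes",
    "gait_intervals",
]


@dataclass
class Trajectory:
    """Per-frame time series of one named keypoint at a fixed frame rate."""

    keypoint: str
    frames: np.ndarray       # strictly increasing frame indices
    points: np.ndarray       # (n, 2) image coordinates
    confidences: np.ndarray  # (n,) in [0, 1]
    frame_rate: float = 25.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.points = np.asarray(self.points, dtype=float)
        self.confidences = np.asarray(self.confidences, dtype=float)
        n = len(self.frames)
        if self.points.shape != (n, 2) or self.confidences.shape != (n,):
            raise ValueError("trajectory arrays must have equal lengths")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @classmethod
    def from_pose_frames(
        cls, frames: Sequence[PoseFrame], keypoint: str, frame_rate: float = 25.0
    ) -> "Trajectory":
        idx = [f.frame_index for f in frames]
        pts, confs = [], []
        for f in frames:
            p, c = f[keypoint]
            pts.append([p.x, p.y])
            confs.append(c)
        return cls(keypoint, np.asarray(idx), np.asarray(pts), np.asarray(confs),
                   frame_rate)


class DistanceSeries(NamedTuple):
    """Per-frame scalar series (e.g. heel-to-heel distance in px)."""

    frames: np.ndarray
    values: np.ndarray


def heel_to_heel_distance(left: Trajectory, right: Trajectory) -> DistanceSeries:
    """Euclidean image distance between the two heels per common frame.

    Frames where either heel is undetected (confidence 0) are filled by
    linear interpolation over frame index from the neighboring valid frames
    (edge values are held at the nearest valid distance).
    """
    common, li, ri = np.intersect1d(left.frames, right.frames,
                                    return_indices=True)
    if common.size == 0:
        raise EmptyOverlapError("trajectories share no common frames")
    lp, rp = left.points[li], right.points[ri]
    dist = np.linalg.norm(lp - rp, axis=1)
    valid = (left.confidences[li] > 0) & (right.confidences[ri] > 0)
    if not valid.any():
        raise EmptyOverlapError("no common frame has both heels detected")
    if not valid.all():
        dist = np.interp(common, common[valid], dist[valid])
    return DistanceSeries(common, dist)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    pad = window // 2
    padded = np.pad(values.astype(float), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: len(values)]


def detect_heel_strikes(
    series: DistanceSeries,
    min_separation_frames: int = 10,
    smoothing_window: int = 3,
    min_prominence: float = 5.0,
) -> list[int]:
    """Frames of heel strikes: prominent local maxima of the smoothed
    heel-to-heel distance.

    Peaks closer than ``min_separation_frames`` are pruned greedily, keeping
    the higher peak (the earlier frame on exact ties).  Returned frame
    indices are sorted ascending.
    """
    frames, values = np.asarray(series[0]), np.asarray(series[1], dtype=float)
    if len(values) <= smoothing_window:
        raise SeriesTooShortError(
            f"series of length {len(values)} not longer than smoothing window "
            f"{smoothing_window}"
        )
    smoothed = _moving_average(values, smoothing_window)
    peaks, _ = signal.find_peaks(smoothed, prominence=min_prominence)
    # greedy non-maximum suppression: by descending height, earlier wins ties
    order = sorted(peaks, key=lambda i: (-smoothed[i], i))
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_separation_frames for j in kept):
            kept.append(i)
    return sorted(int(frames[i]) for i in kept)


def gait_intervals(
    left: Trajectory,
    right: Trajectory,
    speed_threshold: float = 25.0,
    min_duration_s: float = 0.5,
    smoothing_window: int = 5,
) -> list[tuple[int, int]]:
    """Contiguous frame intervals where the subject is walking.

    The mean forward (x) heel position of both feet is smoothed and
    differentiated; runs where its speed magnitude exceeds
    ``speed_threshold`` (px/s) for at least ``min_duration_s`` are returned
    as inclusive ``(start_frame, end_frame)`` pairs.
    """
    common, li, ri = np.intersect1d(left.frames, right.frames,
                                    return_indices=True)
    if common.size < 2:
        raise EmptyOverlapError("need at least two common frames")
    x = 0.5 * (left.points[li, 0] + right.points[ri, 0])
    x = _moving_average(x, smoothing_window)
    v = np.gradient(x, common.astype(float)) * left.frame_rate
    moving = np.abs(v) > speed_threshold
    min_len = int(np.ceil(min_duration_s * left.frame_rate))
    intervals: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(moving):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_len:
                intervals.append((int(common[start]), int(common[i - 1])))
            start = None
    if start is not None and len(moving) - start >= min_len:
        intervals.append((int(common[start]), int(common[-1])))
    return intervals
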