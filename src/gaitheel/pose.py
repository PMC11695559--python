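"""Parsing of 25-keypoint whole-body pose JSON and foot-region cropping.

The upstream pose estimator emits, per video frame, a JSON document with a
``people`` list whose entries carry ``pose_keypoints_2d``: 75 numbers, i.e.
``x, y, confidence`` triplets for the 25 keypoints of the BODY_25 layout.
Confidence 0 marks an undetected keypoint whose coordinates are meaningless.
The foot keypoints (ankle, big toe, heel per side) drive everything
downstream: their centroid locates a fixed 160x120 crop of the foot that the
heel-keypoint networks consume.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    FrameTooSmallError,
    MissingKeypointError,
    PoseDialectError,
    PoseParseError,
)
from .geometry import ImagePoint

__all__ = [
    "BODY25_NAMES",
    "PoseFrame",
    "FootCrop",
    "CROP_WIDTH",
    "CROP_HEIGHT",
    "load_pose_frames",
    "foot_centroid",
    "crop_foot",
]

#: Keypoint names in BODY_25 order.
BODY25_NAMES = (
    "nose", "neck",
    "right_shoulder", "right_elbow", "right_wrist",
    "left_shoulder", "left_elbow", "left_wrist",
    "mid_hip",
    "right_hip", "right_knee", "right_ankle",
    "left_hip", "left_knee", "left_ankle",
    "right_eye", "left_eye", "right_ear", "left_ear",
    "left_big_toe", "left_small_toe", "left_heel",
    "right_big_toe", "right_small_toe", "right_heel",
)

_NAME_TO_INDEX = {n: i for i, n in enumerate(BODY25_NAMES)}

CROP_WIDTH = 160
CROP_HEIGHT = 120

#: The three keypoints whose centroid locates the foot, per body side.
FOOT_KEYPOINTS = {
    "left": ("left_ankle", "left_big_toe", "left_heel"),
    "right": ("right_ankle", "right_big_toe", "right_heel"),
}


@dataclass
class PoseFrame:
    """One frame of 25 named keypoints with per-keypoint confidences."""

    frame_index: int
    points: np.ndarray       # (25, 2) float
    confidences: np.ndarray  # (25,) float in [0, 1]

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.confidences = np.asarray(self.confidences, dtype=float)
        if self.points.shape != (25, 2) or self.confidences.shape != (25,):
            raise PoseDialectError(
                f"frame {self.frame_index}: expected 25 keypoints, got "
                f"{self.points.shape[0] if self.points.ndim == 2 else 'malformed'}"
            )

    def __getitem__(self, name: str) -> tuple[ImagePoint, float]:
        i = _NAME_TO_INDEX[name]
        return ImagePoint(*self.points[i]), float(self.confidences[i])

    def keypoint(self, name: str) -> ImagePoint:
        p, c = self[name]
        if c <= 0:
            raise MissingKeypointError(
                f"frame {self.frame_index}: keypoint '{name}' undetected"
            )
        return p

    @classmethod
    def empty(cls, frame_index: int) -> "PoseFrame":
        """Frame with no detected person: all confidences zero."""
        return cls(frame_index, np.zeros((25, 2)), np.zeros(25))

    @classmethod
    def from_triplets(cls, frame_index: int, flat: Sequence[float]) -> "PoseFrame":
        flat = np.asarray(flat, dtype=float)
        if flat.size != 75:
            raise PoseDialectError(
                f"frame {frame_index}: expected 75 values (25 x,y,c triplets), "
                f"got {flat.size}"
            )
        t = flat.reshape(25, 3)
        return cls(frame_index, t[:, :2].copy(), t[:, 2].copy())

    def to_json_dict(self) -> dict:
        flat = np.column_stack([self.points, self.confidences]).ravel()
        return {"version": 1.3,
                "people": [{"pose_keypoints_2d": [float(v) for v in flat]}]}


@dataclass
class FootCrop:
    """Fixed 160x120 foot image cut out of a full video frame.

    ``origin`` is the full-frame position of the crop's top-left pixel, so a
    crop coordinate maps back to the frame by adding ``origin``.
    """

    pixels: np.ndarray
    origin: ImagePoint
    view: str
    side_of_body: str
    subject_id: str
    frame_index: int

    def __post_init__(self):
        h, w = self.pixels.shape[:2]
        if (w, h) != (CROP_WIDTH, CROP_HEIGHT):
            raise ValueError(f"crop must be {CROP_WIDTH}x{CROP_HEIGHT}, got {w}x{h}")


def _frame_index_from_name(name: str) -> int | None:
    m = re.search(r"(\d+)_keypoints\.json$", name)
    return int(m.group(1)) if m else None


def load_pose_frames(source) -> list[PoseFrame]:
    """Load a sequence of pose frames.

    ``source`` may be a directory of per-frame ``*_keypoints.json`` files
    (sorted by the frame number embedded in the name), a JSON-lines file with
    one frame document per line, or an iterable of already-parsed frame
    dicts.  Person 0 is taken when several people are present; a frame with
    an empty ``people`` list yields an all-zero-confidence frame.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(path.glob("*_keypoints.json"),
                           key=lambda p: (_frame_index_from_name(p.name) is None,
                                          _frame_index_from_name(p.name), p.name))
            frames = []
            for i, f in enumerate(files):
                idx = _frame_index_from_name(f.name)
                frames.append(_parse_frame_doc(_read_json(f), idx if idx is not None else i))
            return frames
        # JSON-lines stream
        frames = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    doc = json.loads(line)
                except json.JSONDecodeError as e:
                    raise PoseParseError(f"frame {i}: invalid JSON: {e}") from e
                frames.append(_parse_frame_doc(doc, i))
        return frames
    return [_parse_frame_doc(doc, i) for i, doc in enumerate(source)]


def _read_json(path: Path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as e:
        raise PoseParseError(f"frame file '{path.name}': invalid JSON: {e}") from e


def _parse_frame_doc(doc: dict, frame_index: int) -> PoseFrame:
    if not isinstance(doc, dict) or "people" not in doc:
        raise PoseParseError(f"frame {frame_index}: missing 'people' field")
    people = doc["people"]
    if not people:
        return PoseFrame.empty(frame_index)
    person = people[0]
    if "pose_keypoints_2d" not in person:
        raise PoseParseError(f"frame {frame_index}: person 0 lacks 'pose_keypoints_2d'")
    return PoseFrame.from_triplets(frame_index, person["pose_keypoints_2d"])


def foot_centroid(frame: PoseFrame, side_of_body: str) -> ImagePoint:
    """Arithmetic mean of the ankle, big-toe and heel keypoints of one foot.

    Raises :class:`MissingKeypointError` if any of the three has confidence 0.
    """
    names = FOOT_KEYPOINTS[side_of_body]
    pts = [frame.keypoint(n) for n in names]
    arr = np.asarray(pts, dtype=float)
    return ImagePoint(*arr.mean(axis=0))


def crop_foot(
    full_frame: np.ndarray,
    centroid: ImagePoint,
    view: str,
    side_of_body: str,
    subject_id: str,
    frame_index: int,
) -> FootCrop:
    """Cut the fixed 160x120 window centered at the rounded centroid.

    A window that would cross a frame edge is shifted by the minimal amount
    needed to fit (no padding), keeping only real pixels; ``origin`` records
    the shift so crop coordinates still map back exactly.
    """
    h, w = full_frame.shape[:2]
    if w < CROP_WIDTH or h < CROP_HEIGHT:
        raise FrameTooSmallError(
            f"frame {w}x{h} smaller than crop {CROP_WIDTH}x{CROP_HEIGHT}"
        )
    cx = int(np.round(centroid[0]))
    cy = int(np.round(centroid[1]))
    ox = min(max(cx - CROP_WIDTH // 2, 0), w - CROP_WIDTH)
    oy = min(max(cy - CROP_HEIGHT // 2, 0), h - CROP_HEIGHT)
    pixels = np.ascontiguousarray(full_frame[oy:oy + CROP_HEIGHT, ox:ox + CROP_WIDTH])
    return FootCrop(pixels, ImagePoint(ox, oy), view, side_of_body,
                    subject_id, frame_index)
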