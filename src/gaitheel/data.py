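"""Labelled heel-keypoint samples: augmentation, subject splits, and IO.

Each labelled sample is a fixed 160x120 foot crop plus the heel keypoint in
crop coordinates.  Augmentation follows the recipe used to build the
training corpus: 20 random window translations per image, drawn uniformly
from a 60-px-wide integer range on each axis, each translated image also
horizontally flipped — a 40x multiplier (originals are kept separately).
Translations re-crop from the source frame rather than shifting pixels, so
no artificial padding enters the training data.

Splitting is by subject: every sample (original or augmented) of a subject
lands in exactly one of train/validation/test, so no subject leaks across
splits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSplitError
from .geometry import ImagePoint
from .pose import CROP_HEIGHT, CROP_WIDTH, FootCrop

__all__ = [
    "LabelledSample",
    "SplitSpec",
    "augment",
    "split_by_subject",
    "write_annotations",
    "read_annotations",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelledSample:
    """A foot crop with its heel keypoint in crop coordinates.

    ``flipped`` and ``translation`` record augmentation provenance;
    originals carry ``flipped=False`` and ``translation=(0, 0)``.
    """

    crop: FootCrop
    heel: ImagePoint
    flipped: bool = False
    translation: tuple[int, int] = (0, 0)

    def __post_init__(self):
        x, y = self.heel
        if not (0 <= x < CROP_WIDTH and 0 <= y < CROP_HEIGHT):
            raise ValueError(f"heel {tuple(self.heel)} outside the "
                             f"{CROP_WIDTH}x{CROP_HEIGHT} crop")

    @property
    def subject_id(self) -> str:
        return self.crop.subject_id


@dataclass(frozen=True)
class SplitSpec:
    """Subject counts for the train/validation/test partition."""

    n_train: int
    n_val: int
    n_test: int
    seed: int = 0

    def __post_init__(self):
        if min(self.n_train, self.n_val, self.n_test) <= 0:
            raise InvalidSplitError("all split counts must be positive")


def _shift_window(frame: np.ndarray, origin_x: int, origin_y: int) -> np.ndarray:
    """Cut the crop window at (origin_x, origin_y); pad by edge replication
    (with a logged warning) only if the window leaves the frame."""
    h, w = frame.shape[:2]
    x0, y0 = origin_x, origin_y
    x1, y1 = x0 + CROP_WIDTH, y0 + CROP_HEIGHT
    if 0 <= x0 and 0 <= y0 and x1 <= w and y1 <= h:
        return np.ascontiguousarray(frame[y0:y1, x0:x1])
    logger.warning(
        "augmentation window (%d, %d) exceeds the %dx%d source frame; "
        "falling back to edge-replication padding", x0, y0, w, h,
    )
    pad_l, pad_t = max(0, -x0), max(0, -y0)
    pad_r, pad_b = max(0, x1 - w), max(0, y1 - h)
    pads = [(pad_t, pad_b), (pad_l, pad_r)] + [(0, 0)] * (frame.ndim - 2)
    padded = np.pad(frame, pads, mode="edge")
    y0 += pad_t
    x0 += pad_l
    return np.ascontiguousarray(padded[y0:y0 + CROP_HEIGHT, x0:x0 + CROP_WIDTH])


def _flip_sample(sample: LabelledSample) -> LabelledSample:
    crop = sample.crop
    flipped_crop = FootCrop(
        np.ascontiguousarray(sample.crop.pixels[:, ::-1]),
        crop.origin, crop.view, crop.side_of_body,
        crop.subject_id, crop.frame_index,
    )
    heel = ImagePoint(CROP_WIDTH - 1 - sample.heel.x, sample.heel.y)
    return LabelledSample(flipped_crop, heel, flipped=True,
                          translation=sample.translation)


def augment(
    sample: LabelledSample,
    source_frame: np.ndarray,
    n_translations: int = 20,
    translation_width: int = 60,
    flip: bool = True,
    rng_seed: int = 0,
) -> list[LabelledSample]:
    """Generate the translated (and flipped) variants of one sample.

    Each translation draws ``(dx, dy)`` independently and uniformly from
    the integers in ``[-translation_width/2, translation_width/2]``; the
    crop window shifts by ``(dx, dy)``, so the heel coordinate shifts by
    ``(-dx, -dy)``.  With ``flip`` on, every translated image is also
    mirrored horizontally (heel x -> width - 1 - x), giving
    ``n_translations * 2`` samples.  The original is not included.
    """
    rng = np.random.default_rng(rng_seed)
    half = translation_width // 2
    base_origin = sample.crop.origin
    out: list[LabelledSample] = []
    for _ in range(n_translations):
        dx = int(rng.integers(-half, half + 1))
        dy = int(rng.integers(-half, half + 1))
        ox = int(round(base_origin.x)) + dx
        oy = int(round(base_origin.y)) + dy
        pixels = _shift_window(source_frame, ox, oy)
        crop = FootCrop(pixels, ImagePoint(ox, oy), sample.crop.view,
                        sample.crop.side_of_body, sample.crop.subject_id,
                        sample.crop.frame_index)
        heel = ImagePoint(sample.heel.x - dx, sample.heel.y - dy)
        translated = LabelledSample(crop, heel, flipped=False,
                                    translation=(dx, dy))
        out.append(translated)
        if flip:
            out.append(_flip_sample(translated))
    return out


def split_by_subject(
    samples: Sequence[LabelledSample], spec: SplitSpec
) -> tuple[list[LabelledSample], list[LabelledSample], list[LabelledSample]]:
    """Partition samples into train/val/test by subject.

    Distinct subject ids are shuffled with ``spec.seed`` and assigned
    ``n_train``/``n_val``/``n_test`` subjects in order; all samples of a
    subject land in exactly one split.
    """
    subjects = sorted({s.subject_id for s in samples})
    total = spec.n_train + spec.n_val + spec.n_test
    if total != len(subjects):
        raise InvalidSplitError(
            f"split counts sum to {total} but there are {len(subjects)} subjects"
        )
    rng = np.random.default_rng(spec.seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    train_ids = set(order[: spec.n_train])
    val_ids = set(order[spec.n_train: spec.n_train + spec.n_val])
    buckets: tuple[list, list, list] = ([], [], [])
    for s in samples:
        if s.subject_id in train_ids:
            buckets[0].append(s)
        elif s.subject_id in val_ids:
            buckets[1].append(s)
        else:
            buckets[2].append(s)
    return buckets


ANNOTATION_COLUMNS = ["subject_id", "view", "frame", "side_of_body", "x", "y"]


def write_annotations(path, samples: Sequence[LabelledSample]):
    """Write heel labels as CSV (integer-pixel coordinates)."""
    rows = [
        {
            "subject_id": s.crop.subject_id,
            "view": s.crop.view,
            "frame": s.crop.frame_index,
            "side_of_body": s.crop.side_of_body,
            "x": int(round(s.heel.x)),
            "y": int(round(s.heel.y)),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    return df


def write_manifest(path, splits: dict[str, Sequence[LabelledSample]]):
    """Record split membership and augmentation provenance as JSON."""
    doc = {
        name: [
            {
                "subject_id": s.crop.subject_id,
                "view": s.crop.view,
                "frame": s.crop.frame_index,
                "side_of_body": s.crop.side_of_body,
                "flipped": s.flipped,
                "translation": list(s.translation),
                "heel": [s.heel.x, s.heel.y],
            }
            for s in samples
        ]
        for name, samples in splits.items()
    }
    Path(path).write_text(json.dumps(doc, indent=1))
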