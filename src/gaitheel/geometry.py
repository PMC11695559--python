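"""Floor-plane calibration: homography estimation and image<->floor projection.

The walking area is calibrated by marking a handful of floor points at known
world positions (cm) and locating them in the image (px).  Because the heel
contact point lies on the floor plane by definition, a single planar
homography suffices to map detected image keypoints to metric floor
coordinates.  Estimation uses the normalized direct linear transform (DLT):
both point sets are Hartley-normalized (zero centroid, mean distance
``sqrt(2)``), the 2n-by-9 linear system is solved by SVD, and the result is
de-normalized and scaled so that ``h[2, 2] = 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import (
    DegenerateConfigurationError,
    InsufficientCorrespondencesError,
    PointAtInfinityError,
)

__all__ = [
    "ImagePoint",
    "FloorPoint",
    "Homography",
    "estimate_homography",
    "project_to_floor",
    "project_to_image",
]


class ImagePoint(NamedTuple):
    """Sub-pixel image position; x is the column (rightward), y the row (down)."""

    x: float
    y: float


class FloorPoint(NamedTuple):
    """Floor position in cm: x along the walking axis, y to the left of it."""

    x: float
    y: float


@dataclass(frozen=True)
class Homography:
    """3x3 projective map from the image plane to the floor plane.

    Stored scale-normalized with ``h[2, 2] = 1``.
    """

    h: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.h, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography must be a 3x3 matrix")
        if not np.all(np.isfinite(m)):
            raise ValueError("homography must be finite")
        if abs(np.linalg.det(m)) < 1e-12:
            raise DegenerateConfigurationError("homography matrix is singular")
        if abs(m[2, 2]) < 1e-12:
            raise ValueError("cannot scale-normalize: h[2,2] is zero")
        object.__setattr__(self, "h", m / m[2, 2])

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.h))

    # -- serialization (row-major JSON, h22 == 1) --

    def to_json(self) -> str:
        return json.dumps({"h": self.h.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Homography":
        return cls(np.asarray(json.loads(text)["h"], dtype=float))


def _hartley_normalization(points: np.ndarray) -> np.ndarray:
    """Similarity transform sending points to zero centroid, RMS-free mean
    distance sqrt(2).  Returns the 3x3 transform."""
    centroid = points.mean(axis=0)
    d = np.linalg.norm(points - centroid, axis=1).mean()
    if d < 1e-12:
        raise DegenerateConfigurationError("all points coincide")
    s = np.sqrt(2.0) / d
    t = np.array([[s, 0.0, -s * centroid[0]],
                  [0.0, s, -s * centroid[1]],
                  [0.0, 0.0, 1.0]])
    return t


def estimate_homography(
    pairs: Sequence[tuple[ImagePoint, FloorPoint]],
) -> Homography:
    """Estimate the image->floor homography from point correspondences.

    Parameters
    ----------
    pairs
        At least four ``(ImagePoint, FloorPoint)`` correspondences from the
        marked floor points; no three floor points may be collinear in a way
        that makes the DLT system rank-deficient.

    Returns
    -------
    Homography
        Minimizer of the algebraic DLT residual on Hartley-normalized
        coordinates, scale-normalized to ``h[2, 2] = 1``.
    """
    if len(pairs) < 4:
        raise InsufficientCorrespondencesError(
            f"homography estimation needs >= 4 correspondences, got {len(pairs)}"
        )
    src = np.asarray([[p[0][0], p[0][1]] for p in pairs], dtype=float)
    dst = np.asarray([[p[1][0], p[1][1]] for p in pairs], dtype=float)
    t_src = _hartley_normalization(src)
    t_dst = _hartley_normalization(dst)
    ones = np.ones((len(pairs), 1))
    sn = (t_src @ np.hstack([src, ones]).T).T
    dn = (t_dst @ np.hstack([dst, ones]).T).T

    a = np.zeros((2 * len(pairs), 9))
    for i, ((sx, sy, _), (dx, dy, _)) in enumerate(zip(sn, dn)):
        a[2 * i] = [-sx, -sy, -1, 0, 0, 0, dx * sx, dx * sy, dx]
        a[2 * i + 1] = [0, 0, 0, -sx, -sy, -1, dy * sx, dy * sy, dy]

    _, sv, vt = np.linalg.svd(a)
    # rank-deficient systems (collinear marks) leave >1 near-null direction
    if sv[7] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError(
            "correspondences are degenerate (collinear or coincident points)"
        )
    hn = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ hn @ t_src
    return Homography(h)


def _project(m: np.ndarray, x: float, y: float) -> tuple[float, float]:
    v = m @ np.array([x, y, 1.0])
    if abs(v[2]) < 1e-12:
        raise PointAtInfinityError(f"point ({x}, {y}) maps to infinity")
    return v[0] / v[2], v[1] / v[2]


def project_to_floor(h: Homography, p: ImagePoint) -> FloorPoint:
    """Project an image point onto the floor plane (cm)."""
    return FloorPoint(*_project(h.h, p[0], p[1]))


def project_to_image(h: Homography, q: FloorPoint) -> ImagePoint:
    """Project a floor point (cm) back into the image (px); inverse of
    :func:`project_to_floor` up to floating-point round-off."""
    return ImagePoint(*_project(np.linalg.inv(h.h), q[0], q[1]))


def load_correspondences(path) -> list[tuple[ImagePoint, FloorPoint]]:
    """Read ``img_x img_y floor_x floor_y`` whitespace-separated lines;
    ``#`` starts a comment."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 numbers, got {len(parts)}")
            ix, iy, fx, fy = map(float, parts)
            pairs.append((ImagePoint(ix, iy), FloorPoint(fx, fy)))
    return pairs


def save_correspondences(path, pairs: Iterable[tuple[ImagePoint, FloorPoint]]):
    with open(path, "w") as fh:
        fh.write("# img_x img_y floor_x floor_y\n")
        for ip, fp in pairs:
            fh.write(f"{ip[0]:.10g} {ip[1]:.10g} {fp[0]:.10g} {fp[1]:.10g}\n")
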