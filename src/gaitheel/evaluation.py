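"""Floor-axis error statistics and step parameters.

The clinically relevant error of a predicted heel keypoint is its distance
from the manual label along one floor axis in world coordinates: the
walking direction (floor x) for side-view images, the lateral direction
(floor y) for frontal-view images — because those axes carry step length
and step width respectively.  Errors are summarized with box-plot
statistics: median, quartiles (linear interpolation of order statistics),
IQR, data extremes, and the fraction of outliers beyond 1.5 x IQR from the
quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .geometry import FloorPoint, Homography, ImagePoint, project_to_floor

__all__ = [
    "ErrorSummary",
    "StepParams",
    "floor_axis_error",
    "summarize_errors",
    "step_parameters",
]


@dataclass(frozen=True)
class ErrorSummary:
    """Box-plot statistics of floor-axis errors (cm)."""

    n: int
    min: float
    max: float
    median: float
    q1: float
    q3: float
    iqr: float
    outlier_fraction: float

    def to_json_dict(self) -> dict:
        return {k: round(v, 3) if isinstance(v, float) else v
                for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class StepParams:
    """Step lengths and widths (cm) from successive heel contacts."""

    step_lengths: tuple[float, ...]
    step_widths: tuple[float, ...]


def floor_axis_error(
    pred: ImagePoint,
    label: ImagePoint,
    crop_origin: ImagePoint,
    h: Homography,
    view: str,
) -> float:
    """Absolute world error along the step-relevant floor axis (cm).

    Both points are given in crop coordinates; they are shifted to
    full-frame coordinates by the crop origin, projected onto the floor,
    and differenced along floor x (side view) or floor y (frontal view).
    """
    if view not in ("side", "frontal"):
        raise InvalidParameterError(f"unknown view '{view}'")
    fp = project_to_floor(h, ImagePoint(pred.x + crop_origin.x,
                                        pred.y + crop_origin.y))
    fl = project_to_floor(h, ImagePoint(label.x + crop_origin.x,
                                        label.y + crop_origin.y))
    if view == "side":
        return abs(fp.x - fl.x)
    return abs(fp.y - fl.y)


def summarize_errors(errors: Sequence[float]) -> ErrorSummary:
    """Box-plot summary with the 1.5 x IQR outlier rule.

    Quartile k sits at rank ``k/4 * (n - 1)`` (0-based) with linear
    interpolation between order statistics; outliers are values above
    ``q3 + 1.5 * iqr`` or below ``q1 - 1.5 * iqr``.
    """
    arr = np.asarray(errors, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("cannot summarize an empty error list")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    n_out = int(np.count_nonzero((arr < lo) | (arr > hi)))
    return ErrorSummary(
        n=int(arr.size),
        min=float(arr.min()),
        max=float(arr.max()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        outlier_fraction=n_out / arr.size,
    )


def step_parameters(heel_floor_points: Sequence[FloorPoint]) -> StepParams:
    """Step lengths and widths from heel floor positions at successive
    (alternating-foot) heel strikes.

    ``step_lengths[i] = |x[i+1] - x[i]|``; ``step_widths[i] = |y[i+1] - y[i]|``.
    """
    if len(heel_floor_points) < 2:
        raise InvalidParameterError("need at least two heel contacts")
    pts = np.asarray([[p[0], p[1]] for p in heel_floor_points], dtype=float)
    d = np.abs(np.diff(pts, axis=0))
    return StepParams(tuple(d[:, 0]), tuple(d[:, 1]))
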