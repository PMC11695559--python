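"""Synthetic fixtures for every pipeline stage.

The clinical recordings behind this method (TUG trials filmed at 25 Hz from
the side and the front) contain sensitive personal data and are not
distributable, so this module generates stand-ins with exact ground truth:

* foot-like silhouettes on textured floor/background with a known heel
  contact point, rendered inside a larger virtual frame so crop windows can
  be shifted for augmentation without padding;
* gait-like 25-keypoint trajectories with heel strikes planted at known
  frames and known step length/width on the floor;
* floor-calibration scenes drawn from a known homography.

All generators are bit-reproducible under a fixed seed, and the ground
truth they return satisfies the geometric definition of the heel keypoint:
the most posterior (side view) or most lateral (frontal view) silhouette
pixel in contact with the floor line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .geometry import (
    FloorPoint,
    Homography,
    ImagePoint,
    project_to_image,
)
from .pose import BODY25_NAMES, PoseFrame

__all__ = [
    "FootSceneParams",
    "GaitScenarioParams",
    "FootFrame",
    "render_foot_image",
    "render_foot_frame",
    "random_foot_params",
    "synth_gait_trajectories",
    "strike_floor_positions",
    "synth_calibration_scene",
    "example_homography",
]

# virtual frame around the 160x120 crop; margins of 80/60 px leave room for
# the +-30 px augmentation shifts on every side
FRAME_WIDTH = 320
FRAME_HEIGHT = 240
CROP_MARGIN_X = (FRAME_WIDTH - 160) // 2
CROP_MARGIN_Y = (FRAME_HEIGHT - 120) // 2


@dataclass(frozen=True)
class FootSceneParams:
    """Geometry of one synthetic foot crop.

    ``heel_position`` is the ground-truth heel keypoint in crop coordinates;
    its row equals ``floor_row`` because the heel keypoint is by definition
    on the floor contact line.  ``foot_length`` is the silhouette extent
    along the floor (its width, for the frontal view).
    """

    foot_length: float
    foot_height: float
    heel_position: ImagePoint
    floor_row: float
    view: str = "side"
    image_width: int = 160
    image_height: int = 120
    texture_seed: int | None = None

    def __post_init__(self):
        hx, hy = self.heel_position
        if not (0 <= hx < self.image_width and 0 <= hy < self.image_height):
            raise InvalidParameterError(
                f"heel position {tuple(self.heel_position)} outside "
                f"{self.image_width}x{self.image_height} image"
            )
        if hy != self.floor_row:
            raise InvalidParameterError(
                "heel keypoint must lie on the floor line: "
                f"heel row {hy} != floor_row {self.floor_row}"
            )
        if not (0 < self.foot_length < self.image_width):
            raise InvalidParameterError(
                f"foot_length {self.foot_length} not in (0, {self.image_width})"
            )
        if self.foot_height <= 0:
            raise InvalidParameterError("foot_height must be positive")
        if self.view not in ("side", "frontal"):
            raise InvalidParameterError(f"unknown view '{self.view}'")


class FootFrame(NamedTuple):
    """A rendered virtual frame with the crop window and ground truth."""

    frame: np.ndarray        # (FRAME_HEIGHT, FRAME_WIDTH, 3) uint8
    mask: np.ndarray         # bool foot silhouette, frame coordinates
    heel_frame: ImagePoint   # heel in frame coordinates
    crop_origin: ImagePoint  # top-left of the 160x120 window


def _blotch_texture(rng: np.random.Generator, shape, sigma: float,
                    amplitude: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    field_ = ndimage.gaussian_filter(noise, sigma)
    peak = np.abs(field_).max()
    return field_ / peak * amplitude if peak > 0 else field_


def _foot_mask(params: FootSceneParams, rng: np.random.Generator,
               heel_frame: tuple[float, float]) -> np.ndarray:
    """Boolean silhouette on the virtual frame grid.

    The sole runs forward (+x) from the heel; the posterior and anterior
    outlines curve forward/backward with randomized curvature, and the whole
    foot is pitched toe-up by a small random angle about the heel so that
    the only floor-contact pixel column is the heel itself (the heel-strike
    posture).  A lower leg rises from the top of the silhouette.
    """
    hx, hy = heel_frame
    length = params.foot_length
    height = params.foot_height
    if params.view == "side":
        theta = np.deg2rad(rng.uniform(0.0, 5.0))
        leg_u = (0.30 * length, 0.58 * length)
    else:
        theta = np.deg2rad(rng.uniform(0.0, 3.0))
        leg_u = (0.25 * length, 0.75 * length)
    c_post = rng.uniform(4.0, 12.0)
    c_toe = rng.uniform(6.0, min(18.0, 0.4 * length))
    lean = rng.uniform(-0.15, 0.25)
    leg_len = rng.uniform(0.8, 1.6) * height + 40.0

    ys, xs = np.mgrid[0:FRAME_HEIGHT, 0:FRAME_WIDTH]
    dx = xs - hx
    dz = hy - ys  # height above the floor line, >= 0 on/above it
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    u = dx * cos_t + dz * sin_t
    w = -dx * sin_t + dz * cos_t
    wc = np.clip(w, 0.0, None)
    frac = np.clip(wc / height, 0.0, 1.0)
    u_min = c_post * frac**2
    u_max = length - c_toe * frac**1.5
    foot = (dz >= 0) & (w >= -1.0) & (w <= height) & (u >= u_min) & (u <= u_max)

    u_leg = u - lean * np.clip(w - height, 0.0, None)
    leg = ((w > height * 0.75) & (w <= height + leg_len)
           & (u_leg >= leg_u[0]) & (u_leg <= leg_u[1]) & (dz >= 0))
    return foot | leg


def _render(params: FootSceneParams, rng_seed: int) -> FootFrame:
    rng = np.random.default_rng(rng_seed)
    tex_rng = (np.random.default_rng(params.texture_seed)
               if params.texture_seed is not None else rng)
    hx, hy = params.heel_position
    heel_frame = (hx + CROP_MARGIN_X, hy + CROP_MARGIN_Y)
    floor_row_frame = params.floor_row + CROP_MARGIN_Y

    mask = _foot_mask(params, rng, heel_frame)
    shape = (FRAME_HEIGHT, FRAME_WIDTH)
    img = np.empty((*shape, 3), dtype=float)

    bg_base = tex_rng.uniform(120, 210, size=3)
    floor_base = tex_rng.uniform(90, 190, size=3)
    foot_base = tex_rng.uniform(15, 95, size=3)
    # keep the foot darker than its surroundings so shape carries the signal
    floor_base = np.maximum(floor_base, foot_base + 50)
    bg_base = np.maximum(bg_base, foot_base + 50)

    bg_tex = _blotch_texture(tex_rng, shape, sigma=9.0,
                             amplitude=tex_rng.uniform(8, 30))
    floor_tex = _blotch_texture(tex_rng, shape, sigma=(1.5, 10.0),
                                amplitude=tex_rng.uniform(8, 30))
    foot_tex = _blotch_texture(tex_rng, shape, sigma=3.0,
                               amplitude=tex_rng.uniform(4, 18))
    shade = 1.0 - 0.25 * (np.arange(FRAME_HEIGHT) / FRAME_HEIGHT)[:, None]

    ys = np.arange(FRAME_HEIGHT)[:, None]
    on_floor = np.broadcast_to(ys > floor_row_frame, shape)
    for c in range(3):
        plane = np.where(on_floor, floor_base[c] + floor_tex,
                         bg_base[c] + bg_tex)
        plane = np.where(mask, (foot_base[c] + foot_tex) * shade, plane)
        img[:, :, c] = plane

    img = ndimage.gaussian_filter(img, sigma=(0.6, 0.6, 0))
    img += rng.normal(0.0, 2.5, size=img.shape)
    frame = np.clip(img, 0, 255).astype(np.uint8)
    origin = ImagePoint(CROP_MARGIN_X, CROP_MARGIN_Y)
    return FootFrame(frame, mask, ImagePoint(*heel_frame), origin)


def render_foot_frame(params: FootSceneParams, rng_seed: int) -> FootFrame:
    """Render the full virtual frame (for augmentation by window shifting)."""
    return _render(params, rng_seed)


def render_foot_image(
    params: FootSceneParams, rng_seed: int
) -> tuple[np.ndarray, ImagePoint]:
    """Render a 160x120 foot crop and return it with its heel keypoint.

    Identical seeds yield bit-identical images.  The returned heel equals
    ``params.heel_position`` and is, by construction, the most posterior
    (side) / most lateral (frontal) silhouette pixel on the floor line.
    """
    scene = _render(params, rng_seed)
    oy, ox = int(scene.crop_origin.y), int(scene.crop_origin.x)
    crop = scene.frame[oy:oy + params.image_height, ox:ox + params.image_width]
    return np.ascontiguousarray(crop), params.heel_position


def random_foot_params(view: str, rng: np.random.Generator) -> FootSceneParams:
    """Draw plausible crop geometry.

    Crops are centered on the ankle/big-toe/heel centroid, which puts the
    heel in the lower-left third of a side-view crop (floor line around
    rows 70-89, heel column around 31-60); keeping the heel at least 30 px
    from every crop edge also guarantees the +-30 px augmentation
    translations never carry the label outside the window.
    """
    floor_row = int(rng.integers(70, 90))
    if view == "side":
        length = float(rng.integers(60, 112))
        height = float(rng.integers(24, 44))
        hx = int(rng.integers(31, max(32, min(61, 150 - int(length)))))
    elif view == "frontal":
        length = float(rng.integers(36, 64))
        height = float(rng.integers(42, 70))
        hx = int(rng.integers(31, 100))
    else:
        raise InvalidParameterError(f"unknown view '{view}'")
    return FootSceneParams(
        foot_length=length,
        foot_height=height,
        heel_position=ImagePoint(hx, floor_row),
        floor_row=floor_row,
        view=view,
    )


# ---------------------------------------------------------------------------
# gait trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitScenarioParams:
    """Ground truth for a synthetic straight-ahead walk.

    Heel strikes alternate feet (left first) at the planted frames; strike
    ``i`` lands at floor x ``start_x + i * step_length_world`` with floor y
    alternating ``+- step_width_world / 2``.
    """

    n_frames: int
    step_period: int
    heel_strike_frames: tuple[int, ...]
    step_length_world: float = 60.0
    step_width_world: float = 10.0
    frame_rate: float = 25.0
    noise_sd: float = 0.0
    start_x: float = 40.0

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.n_frames < 2 * self.step_period:
            raise InvalidParameterError(
                f"n_frames {self.n_frames} < 2 x step_period {self.step_period}"
            )
        strikes = tuple(int(s) for s in self.heel_strike_frames)
        if any(b <= a for a, b in zip(strikes, strikes[1:])):
            raise InvalidParameterError("heel_strike_frames must be strictly increasing")
        if strikes and not (0 <= strikes[0] and strikes[-1] < self.n_frames):
            raise InvalidParameterError("heel_strike_frames must lie in [0, n_frames)")
        object.__setattr__(self, "heel_strike_frames", strikes)

    @classmethod
    def regular(cls, n_frames: int = 120, step_period: int = 15,
                first_strike: int = 20, n_strikes: int | None = None,
                **kwargs) -> "GaitScenarioParams":
        """Evenly spaced strikes every ``step_period`` frames."""
        if n_strikes is None:
            n_strikes = max(0, (n_frames - 2 - first_strike) // step_period + 1)
        strikes = tuple(first_strike + i * step_period for i in range(n_strikes))
        return cls(n_frames=n_frames, step_period=step_period,
                   heel_strike_frames=strikes, **kwargs)


def strike_floor_positions(params: GaitScenarioParams) -> list[FloorPoint]:
    """Planted heel floor positions, one per heel-strike frame."""
    half_w = params.step_width_world / 2.0
    return [
        FloorPoint(params.start_x + i * params.step_length_world,
                   half_w if i % 2 == 0 else -half_w)
        for i in range(len(params.heel_strike_frames))
    ]


def _foot_timelines(params: GaitScenarioParams) -> tuple[np.ndarray, np.ndarray]:
    """Floor x per frame for the left and the right foot.

    Each foot rests where it landed until the *other* foot strikes, then
    swings linearly to its next landing spot, arriving exactly on its strike
    frame.  This makes the heel-to-heel distance strictly increase into
    every strike frame and strictly decrease right after it, so its local
    maxima sit exactly on the planted strikes.
    """
    strikes = list(params.heel_strike_frames)
    length = params.step_length_world
    gap_first = strikes[1] - strikes[0] if len(strikes) > 1 else params.step_period
    gap_last = strikes[-1] - strikes[-2] if len(strikes) > 1 else params.step_period
    x_of = lambda i: params.start_x + i * length

    # events: (frame, floor x, foot parity).  Two virtual landings before the
    # first strike start the walk; one closing event after the last strike
    # brings the trailing foot to rest just behind the leading one, so the
    # heel-to-heel distance peaks at every planted strike and nowhere else.
    events = [(strikes[0] - 2 * gap_first, x_of(-2), 0),
              (strikes[0] - gap_first, x_of(-1), 1)]
    events += [(f, x_of(i), i % 2) for i, f in enumerate(strikes)]
    # the closing step covers 0.8 L in 0.4 gap frames, matching the 2 L / gap
    # approach speed so moving-average smoothing cannot shift the last peak
    k_last = len(strikes) - 1
    close_dur = max(2, round(0.4 * gap_last))
    events.append((strikes[-1] + close_dur, x_of(k_last) - 0.2 * length,
                   (k_last + 1) % 2))

    n = params.n_frames
    t = np.arange(n)
    x_feet = np.zeros((2, n))
    for foot in (0, 1):  # 0 = left (even strike indices), 1 = right
        x = np.full(n, np.nan)
        own = [(f, xx) for f, xx, p in events if p == foot]
        frames_all = [f for f, _, _ in events]
        for (f0, x0), (f1, x1) in zip(own, own[1:]):
            # planted at x0 until the other foot lands in between, then a
            # linear swing arriving exactly on the own landing frame
            mids = [f for f in frames_all if f0 < f < f1]
            pivot = mids[0] if mids else f0
            for fr in range(max(f0, 0), min(f1, n - 1) + 1):
                if fr <= pivot:
                    x[fr] = x0
                else:
                    x[fr] = x0 + (fr - pivot) / (f1 - pivot) * (x1 - x0)
        # hold the end states outside the covered range
        valid = ~np.isnan(x)
        x = np.interp(t, t[valid], x[valid])
        x_feet[foot] = x
    return x_feet[0], x_feet[1]


_FOOT_KP = {
    "left": ("left_heel", "left_big_toe", "left_small_toe", "left_ankle"),
    "right": ("right_heel", "right_big_toe", "right_small_toe", "right_ankle"),
}


def synth_gait_trajectories(
    params: GaitScenarioParams,
    homography: Homography,
    rng_seed: int,
) -> tuple[list[PoseFrame], GaitScenarioParams]:
    """Generate 25-keypoint pose frames for a straight walk.

    Heel floor positions follow stance plateaus with linear swing
    transitions; they are mapped into the image through the inverse of
    ``homography`` (image -> floor), so heel image positions at the strike
    frames project back exactly onto the planted floor points.  Gaussian
    image noise of ``params.noise_sd`` px is added to the foot keypoints.
    """
    rng = np.random.default_rng(rng_seed)
    left_x, right_x = _foot_timelines(params)
    half_w = params.step_width_world / 2.0
    y_floor = {"left": half_w, "right": -half_w}
    name_idx = {n: i for i, n in enumerate(BODY25_NAMES)}

    frames: list[PoseFrame] = []
    for fr in range(params.n_frames):
        pts = np.zeros((25, 2))
        conf = np.zeros(25)
        for side, foot_x in (("left", left_x), ("right", right_x)):
            hx = foot_x[fr]
            hy = y_floor[side]
            heel_img = project_to_image(homography, FloorPoint(hx, hy))
            toe_img = project_to_image(homography, FloorPoint(hx + 24.0, hy))
            small_img = project_to_image(
                homography,
                FloorPoint(hx + 20.0, hy + (4.0 if side == "left" else -4.0)))
            ankle_img = project_to_image(homography, FloorPoint(hx + 6.0, hy))
            coords = {
                f"{side}_heel": heel_img,
                f"{side}_big_toe": toe_img,
                f"{side}_small_toe": small_img,
                f"{side}_ankle": ImagePoint(ankle_img.x, ankle_img.y - 18.0),
            }
            for name, p in coords.items():
                i = name_idx[name]
                jitter = rng.normal(0.0, params.noise_sd, size=2) \
                    if params.noise_sd > 0 else np.zeros(2)
                pts[i] = [p.x + jitter[0], p.y + jitter[1]]
                conf[i] = 0.95
        frames.append(PoseFrame(fr, pts, conf))
    return frames, params


# ---------------------------------------------------------------------------
# calibration scenes
# ---------------------------------------------------------------------------

def synth_calibration_scene(
    true_h: Homography,
    n_points: int,
    noise_sd: float,
    rng_seed: int,
    floor_extent: tuple[float, float] = (300.0, 200.0),
) -> list[tuple[ImagePoint, FloorPoint]]:
    """Image/floor correspondences drawn from a known homography.

    Floor points are jittered grid nodes inside ``floor_extent`` cm (so they
    are never collinear); image points are their exact projections plus
    Gaussian noise of ``noise_sd`` px.  With ``noise_sd = 0`` every pair
    satisfies the projective relation under ``true_h`` exactly.
    """
    if n_points < 4:
        raise InvalidParameterError(
            f"calibration needs >= 4 points, got {n_points}"
        )
    rng = np.random.default_rng(rng_seed)
    cols = int(np.ceil(np.sqrt(n_points)))
    rows = int(np.ceil(n_points / cols))
    cells = [(i, j) for i in range(cols) for j in range(rows)]
    chosen = rng.choice(len(cells), size=n_points, replace=False)
    sx, sy = floor_extent[0] / cols, floor_extent[1] / rows
    pairs = []
    for k in chosen:
        i, j = cells[k]
        fx = (i + 0.5 + rng.uniform(-0.3, 0.3)) * sx
        fy = (j + 0.5 + rng.uniform(-0.3, 0.3)) * sy
        fp = FloorPoint(fx, fy)
        ip = project_to_image(true_h, fp)
        if noise_sd > 0:
            ip = ImagePoint(ip.x + rng.normal(0, noise_sd),
                            ip.y + rng.normal(0, noise_sd))
        pairs.append((ip, fp))
    return pairs


def example_homography() -> Homography:
    """A plausible side-view camera: floor cm -> image px with mild
    perspective, inverted to the image -> floor convention."""
    g = np.array([
        [4.5, 1.0, 200.0],
        [0.05, -1.2, 700.0],
        [0.0, -0.0012, 1.0],
    ])
    return Homography(np.linalg.inv(g))


def make_labelled_samples(
    n_subjects: int,
    crops_per_subject: int,
    view: str,
    rng_seed: int,
) -> list:
    """Labelled foot crops for training experiments.

    Each crop is an independently drawn scene (geometry + textures) tagged
    with a synthetic subject id, so subject-wise splitting works as it does
    for real recordings.
    """
    from .data import LabelledSample  # local import: data depends on pose only
    from .pose import FootCrop

    rng = np.random.default_rng(rng_seed)
    samples = []
    for s in range(n_subjects):
        subject = f"synth{s:04d}"
        for k in range(crops_per_subject):
            params = random_foot_params(view, rng)
            seed = int(rng.integers(2**31))
            image, heel = render_foot_image(params, seed)
            crop = FootCrop(image, ImagePoint(CROP_MARGIN_X, CROP_MARGIN_Y),
                            view, "left", subject, k)
            samples.append(LabelledSample(crop, heel))
    return samples
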