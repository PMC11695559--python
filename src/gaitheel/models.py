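"""Heel-keypoint network variants: backbone x head construction, target
heatmap rendering, heatmap decoding and keypoint prediction.

Two head designs sit on the three backbones:

* **regression head** — the full backbone with its 1000-way output,
  followed by a fully connected 1000 -> 2 layer giving the heel's
  normalized ``(x / width, y / height)`` crop coordinates;
* **heatmap head** — the backbone's feature-extraction layers followed by
  five transposed convolutional layers (stride 2 each) that restore the
  spatial resolution to near the 160x120 input, and a final 1x1
  convolution down to a single channel.  The keypoint is decoded as the
  intensity-weighted mean position inside a 13x13 neighborhood around the
  heatmap maximum.

Supervision targets for the heatmap head are isotropic Gaussians (sigma 3
px by default) rendered on the head's output grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .backbones import BACKBONES, build_backbone
from .errors import InvalidParameterError, InvalidSpecError, UndecodableHeatmapError
from .geometry import ImagePoint
from .pose import CROP_HEIGHT, CROP_WIDTH, FootCrop

__all__ = [
    "ModelSpec",
    "Heatmap",
    "GaitHeelModel",
    "build_model",
    "count_parameters",
    "render_target_heatmap",
    "decode_heatmap",
    "predict_keypoint",
    "save_checkpoint",
    "load_checkpoint",
]

DECODE_NEIGHBORHOOD = 13

# channel widths of the five transposed-convolution layers; chosen narrow
# enough that desk-scale CPU training stays tractable while the last layers
# still carry enough channels to shape a single-keypoint response map
DEFAULT_HEAD_CHANNELS = (64, 48, 32, 16, 8)

# ImageNet channel statistics used to standardize inputs
_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one backbone x head variant."""

    backbone: str
    head: str
    pretrained: bool = False
    input_size: tuple[int, int] = (CROP_WIDTH, CROP_HEIGHT)  # (width, height)
    heatmap_sigma: float = 3.0
    head_channels: tuple[int, ...] = DEFAULT_HEAD_CHANNELS
    dropout: float = 0.5

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise InvalidSpecError(
                f"unknown backbone '{self.backbone}' (choose from {BACKBONES})")
        if self.head not in ("regression", "heatmap"):
            raise InvalidSpecError(f"unknown head '{self.head}'")
        if tuple(self.input_size) != (CROP_WIDTH, CROP_HEIGHT):
            raise InvalidSpecError(
                f"input size is fixed at {CROP_WIDTH}x{CROP_HEIGHT}")
        if self.heatmap_sigma <= 0:
            raise InvalidSpecError("heatmap_sigma must be positive")
        if len(self.head_channels) != 5:
            raise InvalidSpecError("heatmap head uses exactly five upsampling layers")

    def to_json_dict(self) -> dict:
        return {
            "backbone": self.backbone,
            "head": self.head,
            "pretrained": self.pretrained,
            "heatmap_sigma": self.heatmap_sigma,
            "head_channels": list(self.head_channels),
            "dropout": self.dropout,
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "ModelSpec":
        doc = dict(doc)
        if "head_channels" in doc:
            doc["head_channels"] = tuple(doc["head_channels"])
        return cls(**doc)


@dataclass
class Heatmap:
    """Single-channel nonnegative response map over a grid near input
    resolution; ``grid_to_input_scale = (sx, sy)`` maps grid coordinates to
    input-crop pixel coordinates."""

    values: np.ndarray
    grid_to_input_scale: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidParameterError("heatmap must be a non-empty 2D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("heatmap values must be finite")
        sx, sy = self.grid_to_input_scale
        if sx <= 0 or sy <= 0:
            raise InvalidParameterError("scale factors must be positive")


@dataclass
class GaitHeelModel:
    """A built model: engine network plus its specification and the output
    grid geometry of the heatmap head (None for the regression head)."""

    spec: ModelSpec
    network: nn.Module
    output_grid: tuple[int, int] | None = None  # (height, width)

    @property
    def grid_to_input_scale(self) -> tuple[float, float] | None:
        if self.output_grid is None:
            return None
        gh, gw = self.output_grid
        return (CROP_WIDTH / gw, CROP_HEIGHT / gh)

    def forward(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        return self.network.forward(batch, training)


def build_model(spec: ModelSpec, rng_seed: int = 0) -> GaitHeelModel:
    """Construct one of the six backbone x head variants.

    ``spec.pretrained`` requests ImageNet-pretrained backbone weights; they
    are an optional initialization loaded from a user-supplied checkpoint
    (see :func:`load_checkpoint`), so ``build_model`` itself always starts
    from random initialization and raises if asked otherwise.
    """
    if spec.pretrained:
        raise InvalidSpecError(
            "pretrained initialization is loaded from a checkpoint file via "
            "load_checkpoint(); build_model always initializes randomly")
    rng = np.random.default_rng(rng_seed)
    if spec.head == "regression":
        backbone = build_backbone(spec.backbone, "classifier",
                                  rng_seed=int(rng.integers(2**31)))
        head = nn.Sequential(
            nn.Dropout(spec.dropout, rng=np.random.default_rng(rng.integers(2**31))),
            nn.Linear(1000, 2, rng=np.random.default_rng(rng.integers(2**31))),
        )
        network = nn.Sequential(backbone.network, head)
        return GaitHeelModel(spec, network, output_grid=None)

    backbone = build_backbone(spec.backbone, "features",
                              rng_seed=int(rng.integers(2**31)))
    layers: list[nn.Module] = []
    cin = backbone.feature_channels
    up_rng = np.random.default_rng(rng.integers(2**31))
    for cout in spec.head_channels:
        layers += [
            nn.ConvTranspose2d(cin, cout, 4, stride=2, padding=1, rng=up_rng),
            nn.BatchNorm2d(cout),
            nn.ReLU(),
        ]
        cin = cout
    # dropout after the normalized stack (before any batchnorm it would skew
    # the running statistics the inference path relies on)
    layers.append(nn.Dropout(spec.dropout,
                             rng=np.random.default_rng(rng.integers(2**31))))
    layers.append(nn.Conv2d(cin, 1, 1, rng=up_rng))
    network = nn.Sequential(backbone.network, nn.Sequential(*layers))
    # feature grid for the fixed input, then five stride-2 upsamplings
    fh, fw = CROP_HEIGHT, CROP_WIDTH
    probe = network.modules[0].forward(
        np.zeros((1, 3, fh, fw), dtype=np.float32))
    gh, gw = probe.shape[2] * 32, probe.shape[3] * 32
    return GaitHeelModel(spec, network, output_grid=(gh, gw))


def count_parameters(model) -> int:
    """Total trainable parameter count of a built model (or bare module)."""
    net = model.network if isinstance(model, GaitHeelModel) else model
    return int(sum(p.size for p in net.parameters()))


def render_target_heatmap(
    heel: ImagePoint,
    shape: tuple[int, int],
    sigma: float,
    grid_to_input_scale: tuple[float, float] = (1.0, 1.0),
) -> Heatmap:
    """Isotropic Gaussian bump centered on the heel keypoint.

    ``heel`` is given in grid coordinates of the ``shape = (h, w)`` grid;
    values follow ``exp(-((x-hx)^2 + (y-hy)^2) / (2 sigma^2))`` normalized
    so the peak value is exactly 1 at the grid point nearest the keypoint.
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    h, w = shape
    hx, hy = heel
    if not (0 <= hx <= w - 1 and 0 <= hy <= h - 1):
        raise InvalidParameterError(
            f"heel {(hx, hy)} outside the {h}x{w} heatmap grid")
    ys = np.arange(h)[:, None]
    xs = np.arange(w)[None, :]
    d2 = (xs - hx) ** 2 + (ys - hy) ** 2
    values = np.exp(-d2 / (2.0 * sigma * sigma))
    values /= values.max()
    return Heatmap(values, grid_to_input_scale)


def decode_heatmap(hm: Heatmap) -> ImagePoint:
    """Decode a heatmap to a sub-pixel keypoint in input-crop coordinates.

    Negative responses are clamped to zero; the global maximum is located
    (ties -> smallest row-major index) and the intensity-weighted mean
    position over the 13x13 window centered there (clipped at borders) is
    scaled to input coordinates.
    """
    values = np.maximum(hm.values, 0.0)
    if values.max() <= 0:
        raise UndecodableHeatmapError("heatmap has no positive response")
    h, w = values.shape
    flat_idx = int(np.argmax(values))
    r0, c0 = divmod(flat_idx, w)
    half = DECODE_NEIGHBORHOOD // 2
    r_lo, r_hi = max(0, r0 - half), min(h, r0 + half + 1)
    c_lo, c_hi = max(0, c0 - half), min(w, c0 + half + 1)
    window = values[r_lo:r_hi, c_lo:c_hi]
    total = window.sum()
    ys = np.arange(r_lo, r_hi)[:, None]
    xs = np.arange(c_lo, c_hi)[None, :]
    gx = float((window * xs).sum() / total)
    gy = float((window * ys).sum() / total)
    sx, sy = hm.grid_to_input_scale
    return ImagePoint(gx * sx, gy * sy)


def preprocess(image: np.ndarray) -> np.ndarray:
    """uint8 crop (H, W[, 3]) -> standardized float32 (3, H, W)."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    x = arr.astype(np.float32) / 255.0
    x = (x - _MEAN) / _STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def predict_keypoint(model: GaitHeelModel, crop) -> ImagePoint:
    """Predict the heel keypoint of one 160x120 crop, in crop coordinates."""
    pixels = crop.pixels if isinstance(crop, FootCrop) else crop
    h, w = pixels.shape[:2]
    if (w, h) != (CROP_WIDTH, CROP_HEIGHT):
        raise InvalidParameterError(
            f"crop must be {CROP_WIDTH}x{CROP_HEIGHT}, got {w}x{h}")
    batch = preprocess(pixels)[None]
    out = model.forward(batch, training=False)
    if model.spec.head == "regression":
        u, v = float(out[0, 0]), float(out[0, 1])
        return ImagePoint(u * CROP_WIDTH, v * CROP_HEIGHT)
    hm = Heatmap(out[0, 0], model.grid_to_input_scale)
    return decode_heatmap(hm)


def save_checkpoint(path, model: GaitHeelModel):
    """Serialize spec + weights (npz alongside a small JSON header)."""
    arrays = model.network.state_arrays()
    meta = json.dumps(model.spec.to_json_dict())
    np.savez(path, __spec__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{f"arr_{i}": a for i, a in enumerate(arrays)})


def load_checkpoint(path) -> GaitHeelModel:
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__spec__"]).decode())
        spec = ModelSpec.from_json_dict(meta)
        model = build_model(spec)
        arrays = [zf[f"arr_{i}"]
                  for i in range(len(model.network.state_arrays()))]
    model.network.load_state_arrays(arrays)
    return model
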