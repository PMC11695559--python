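"""Standard convnet backbones built on the package's NN engine.

Three ImageNet-class architectures are reproduced layer-for-layer so that
their parameter counts match the published originals: VGG19, ResNeXt-50
(32x4d) and MobileNetV2.  Each is available in two trims:

* ``classifier`` — the full network ending in the 1000-way ImageNet output
  (used under the regression head, which maps those 1000 features to the
  two normalized keypoint coordinates);
* ``features`` — the feature-extraction layers only (VGG19: its 16
  convolutional layers; MobileNetV2 and ResNeXt-50: everything up to the
  global pooling), used under the heatmap head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["BACKBONES", "Backbone", "build_backbone"]


@dataclass
class Backbone:
    """A built backbone with its metadata."""

    name: str
    trim: str                 # "classifier" | "features"
    network: nn.Module
    feature_channels: int     # channels at the features output
    downsampling: int         # spatial stride of the features output


def _conv_bn_relu6(cin, cout, k, stride, rng, groups=1, dtype=np.float32):
    return [
        nn.Conv2d(cin, cout, k, stride=stride, padding=(k - 1) // 2,
                  groups=groups, bias=False, rng=rng, dtype=dtype),
        nn.BatchNorm2d(cout, dtype=dtype),
        nn.ReLU6(),
    ]


# ---------------------------------------------------------------------------
# VGG19
# ---------------------------------------------------------------------------

_VGG19_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]


def _vgg19(trim, rng, dtype):
    layers: list[nn.Module] = []
    cin = 3
    for v in _VGG19_CFG:
        if v == "M":
            layers.append(nn.MaxPool2d(2))
        else:
            layers.append(nn.Conv2d(cin, v, 3, padding=1, rng=rng, dtype=dtype))
            layers.append(nn.ReLU())
            cin = v
    if trim == "features":
        return nn.Sequential(*layers), 512
    layers += [
        nn.AdaptiveAvgPool2d((7, 7)),
        nn.Flatten(),
        nn.Linear(512 * 7 * 7, 4096, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Linear(4096, 4096, rng=rng, dtype=dtype),
        nn.ReLU(),
        nn.Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Linear(4096, 1000, rng=rng, dtype=dtype),
    ]
    return nn.Sequential(*layers), 512


# ---------------------------------------------------------------------------
# MobileNetV2
# ---------------------------------------------------------------------------

# (expansion t, output channels c, repeats n, first stride s)
_MBV2_SETTINGS = [
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
]


def _inverted_residual(cin, cout, stride, expand, rng, dtype):
    hidden = cin * expand
    layers: list[nn.Module] = []
    if expand != 1:
        layers += _conv_bn_relu6(cin, hidden, 1, 1, rng, dtype=dtype)
    layers += _conv_bn_relu6(hidden, hidden, 3, stride, rng,
                             groups=hidden, dtype=dtype)
    layers += [
        nn.Conv2d(hidden, cout, 1, bias=False, rng=rng, dtype=dtype),
        nn.BatchNorm2d(cout, dtype=dtype),
    ]
    block = nn.Sequential(*layers)
    if stride == 1 and cin == cout:
        return nn.Residual(block)
    return block


def _mobilenetv2(trim, rng, dtype):
    layers: list[nn.Module] = _conv_bn_relu6(3, 32, 3, 2, rng, dtype=dtype)
    cin = 32
    for t, c, n, s in _MBV2_SETTINGS:
        for i in range(n):
            layers.append(_inverted_residual(cin, c, s if i == 0 else 1, t,
                                             rng, dtype))
            cin = c
    layers += _conv_bn_relu6(cin, 1280, 1, 1, rng, dtype=dtype)
    if trim == "features":
        return nn.Sequential(*layers), 1280
    layers += [
        nn.AdaptiveAvgPool2d((1, 1)),
        nn.Flatten(),
        nn.Dropout(0.2, rng=np.random.default_rng(rng.integers(2**31))),
        nn.Linear(1280, 1000, rng=rng, dtype=dtype),
    ]
    return nn.Sequential(*layers), 1280


# ---------------------------------------------------------------------------
# ResNeXt-50 (32x4d)
# ---------------------------------------------------------------------------

def _resnext_bottleneck(cin, planes, stride, rng, dtype,
                        groups=32, width_per_group=4, expansion=4):
    width = planes * width_per_group // 64 * groups
    cout = planes * expansion
    main = nn.Sequential(
        nn.Conv2d(cin, width, 1, bias=False, rng=rng, dtype=dtype),
        nn.BatchNorm2d(width, dtype=dtype),
        nn.ReLU(),
        nn.Conv2d(width, width, 3, stride=stride, padding=1, groups=groups,
                  bias=False, rng=rng, dtype=dtype),
        nn.BatchNorm2d(width, dtype=dtype),
        nn.ReLU(),
        nn.Conv2d(width, cout, 1, bias=False, rng=rng, dtype=dtype),
        nn.BatchNorm2d(cout, dtype=dtype),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = nn.Sequential(
            nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng,
                      dtype=dtype),
            nn.BatchNorm2d(cout, dtype=dtype),
        )
    return nn.Residual(main, shortcut, post=nn.ReLU())


def _resnext50(trim, rng, dtype):
    layers: list[nn.Module] = [
        nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng,
                  dtype=dtype),
        nn.BatchNorm2d(64, dtype=dtype),
        nn.ReLU(),
        nn.MaxPool2d(3, stride=2, padding=1),
    ]
    cin = 64
    for planes, blocks, stride in [(64, 3, 1), (128, 4, 2),
                                   (256, 6, 2), (512, 3, 2)]:
        for i in range(blocks):
            layers.append(_resnext_bottleneck(cin, planes,
                                              stride if i == 0 else 1,
                                              rng, dtype))
            cin = planes * 4
    if trim == "features":
        return nn.Sequential(*layers), 2048
    layers += [
        nn.AdaptiveAvgPool2d((1, 1)),
        nn.Flatten(),
        nn.Linear(2048, 1000, rng=rng, dtype=dtype),
    ]
    return nn.Sequential(*layers), 2048


_BUILDERS = {
    "vgg19": _vgg19,
    "mobilenetv2": _mobilenetv2,
    "resnext50": _resnext50,
}

BACKBONES = tuple(_BUILDERS)


def build_backbone(name: str, trim: str = "classifier", rng_seed: int = 0,
                   dtype=np.float32) -> Backbone:
    """Construct a backbone by name.

    ``trim='classifier'`` yields the full 1000-way network; ``'features'``
    keeps only the feature-extraction layers (output stride 32).
    """
    if name not in _BUILDERS:
        raise KeyError(f"unknown backbone '{name}' (choose from {BACKBONES})")
    if trim not in ("classifier", "features"):
        raise ValueError(f"unknown trim '{trim}'")
    rng = np.random.default_rng(rng_seed)
    network, channels = _BUILDERS[name](trim, rng, dtype)
    return Backbone(name, trim, network, channels, downsampling=32)
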