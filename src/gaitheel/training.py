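"""Training loop for the heel-keypoint networks.

Optimization follows the protocol the models were tuned with: SGD with
momentum 0.9 and weight decay 1e-4, mean-square error of the prediction as
the loss (on normalized coordinates for the regression head, per-pixel on
heatmaps for the heatmap head), learning rate decayed by 0.1 after 10
epochs, at most 20 epochs with early stopping at patience 4 on the
validation loss, dropout 0.5 in the head.  The weights of the best
validation epoch are restored at the end.  Side-view and frontal-view
models are always trained separately (the foot looks entirely different in
the two views), so the trainer carries a view tag and refuses mixed-view
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import LabelledSample
from .errors import DivergenceError, InvalidParameterError
from .geometry import ImagePoint
from .models import (
    GaitHeelModel,
    Heatmap,
    decode_heatmap,
    preprocess,
    render_target_heatmap,
)
from .nn import SGD
from .pose import CROP_HEIGHT, CROP_WIDTH

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "loss",
    "train",
    "predict_batch",
    "keypoint_errors",
    "simulate_early_stopping",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_decay_factor: float = 0.1
    lr_decay_epoch: int = 10
    patience: int = 4
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        positives = dict(epochs=self.epochs, batch_size=self.batch_size,
                         lr=self.lr, lr_decay_factor=self.lr_decay_factor,
                         lr_decay_epoch=self.lr_decay_epoch,
                         patience=self.patience)
        for name, v in positives.items():
            if v <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {v}")
        if self.patience >= self.epochs:
            raise InvalidParameterError("patience must be smaller than epochs")

    def lr_at(self, epoch: int) -> float:
        """Learning rate in force during 1-based ``epoch`` (decayed after
        ``lr_decay_epoch`` full epochs)."""
        return self.lr * (self.lr_decay_factor
                          if epoch > self.lr_decay_epoch else 1.0)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean of squared differences over all components."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise InvalidParameterError(
            f"prediction shape {p.shape} != target shape {t.shape}")
    return float(np.mean((p - t) ** 2))


def simulate_early_stopping(val_losses: Sequence[float],
                            patience: int) -> tuple[int, int]:
    """Apply the early-stopping rule to a validation-loss trace.

    "Did not decrease" means not strictly lower than the best value seen so
    far.  Returns (1-based epoch after which training stops, 1-based epoch
    of the best validation loss).  If the trace never triggers the rule the
    stop epoch is ``len(val_losses)``.
    """
    best = np.inf
    best_epoch = 0
    since_improve = 0
    for epoch, v in enumerate(val_losses, start=1):
        if v < best:
            best, best_epoch, since_improve = v, epoch, 0
        else:
            since_improve += 1
        if since_improve >= patience:
            return epoch, best_epoch
    return len(val_losses), best_epoch


def _prepare(model: GaitHeelModel, samples: Sequence[LabelledSample]):
    """Stack preprocessed inputs and per-head targets for a dataset."""
    views = {s.crop.view for s in samples}
    if len(views) > 1:
        raise InvalidParameterError(
            f"side and frontal crops must train separate models, got {views}")
    x = np.stack([preprocess(s.crop.pixels) for s in samples])
    if model.spec.head == "regression":
        y = np.array([[s.heel.x / CROP_WIDTH, s.heel.y / CROP_HEIGHT]
                      for s in samples], dtype=np.float32)
    else:
        gh, gw = model.output_grid
        sx, sy = model.grid_to_input_scale
        maps = [
            render_target_heatmap(
                ImagePoint(s.heel.x / sx, s.heel.y / sy), (gh, gw),
                model.spec.heatmap_sigma).values
            for s in samples
        ]
        y = np.asarray(maps, dtype=np.float32)[:, None]  # (n, 1, gh, gw)
    return x, y


def _batch_loss_and_grad(out: np.ndarray, target: np.ndarray):
    diff = out - target
    value = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return value, grad.astype(out.dtype)


def train(
    model: GaitHeelModel,
    train_set: Sequence[LabelledSample],
    val_set: Sequence[LabelledSample],
    cfg: TrainConfig,
) -> tuple[GaitHeelModel, TrainHistory]:
    """Train ``model`` in place and return it with its history.

    Fully reproducible under a fixed seed on a fixed device: mini-batch
    shuffling and dropout are the only stochastic elements and both derive
    from ``cfg.seed`` and the model's build seed.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise InvalidParameterError("train and validation sets must be non-empty")
    x_train, y_train = _prepare(model, train_set)
    x_val, y_val = _prepare(model, val_set)

    params = model.network.parameters()
    opt = SGD(params, lr=cfg.lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    best_val = np.inf
    best_state = None
    since_improve = 0

    n = len(train_set)
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            out = model.network.forward(x_train[idx], training=True)
            value, grad = _batch_loss_and_grad(out, y_train[idx])
            if not np.isfinite(value):
                raise DivergenceError(epoch)
            opt.zero_grad()
            model.network.backward(grad)
            opt.step()
            epoch_losses.append(value)

        val = _dataset_loss(model, x_val, y_val, cfg.batch_size)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val)
        history.lr.append(opt.lr)

        if val < best_val:
            best_val, since_improve = val, 0
            history.best_epoch = epoch
            best_state = [a.copy() for a in model.network.state_arrays()]
        else:
            since_improve += 1
        if since_improve >= cfg.patience:
            break

    history.stopped_epoch = len(history.val_loss)
    if best_state is not None:
        model.network.load_state_arrays(best_state)
    return model, history


def _dataset_loss(model: GaitHeelModel, x: np.ndarray, y: np.ndarray,
                  batch_size: int) -> float:
    total, count = 0.0, 0
    for start in range(0, len(x), batch_size):
        out = model.network.forward(x[start:start + batch_size],
                                    training=False)
        t = y[start:start + batch_size]
        total += float(np.sum((out.astype(np.float64) - t) ** 2))
        count += t.size
    return total / count


def predict_batch(model: GaitHeelModel,
                  samples: Sequence[LabelledSample],
                  batch_size: int = 16) -> list[ImagePoint]:
    """Predicted heel keypoints (crop coordinates) for a list of samples."""
    x = np.stack([preprocess(s.crop.pixels) for s in samples])
    preds: list[ImagePoint] = []
    for start in range(0, len(x), batch_size):
        out = model.network.forward(x[start:start + batch_size],
                                    training=False)
        if model.spec.head == "regression":
            for u, v in out:
                preds.append(ImagePoint(float(u) * CROP_WIDTH,
                                        float(v) * CROP_HEIGHT))
        else:
            for hm_values in out[:, 0]:
                preds.append(decode_heatmap(
                    Heatmap(hm_values, model.grid_to_input_scale)))
    return preds


def keypoint_errors(model: GaitHeelModel,
                    samples: Sequence[LabelledSample],
                    batch_size: int = 16) -> np.ndarray:
    """Euclidean crop-pixel error between prediction and label per sample.

    A sample whose response map is undecodable (no positive response) is
    scored with the worst possible error for its label — the distance to
    the farthest crop corner — so the metric stays defined for degenerate
    models instead of raising.
    """
    from .errors import UndecodableHeatmapError

    x = np.stack([preprocess(s.crop.pixels) for s in samples])
    errors = np.empty(len(samples))
    k = 0
    for start in range(0, len(x), batch_size):
        out = model.network.forward(x[start:start + batch_size],
                                    training=False)
        for row in out:
            s = samples[k]
            if model.spec.head == "regression":
                p = ImagePoint(float(row[0]) * CROP_WIDTH,
                               float(row[1]) * CROP_HEIGHT)
            else:
                try:
                    p = decode_heatmap(Heatmap(row[0],
                                               model.grid_to_input_scale))
                except UndecodableHeatmapError:
                    corners = [(0, 0), (CROP_WIDTH - 1, 0),
                               (0, CROP_HEIGHT - 1),
                               (CROP_WIDTH - 1, CROP_HEIGHT - 1)]
                    errors[k] = max(np.hypot(cx - s.heel.x, cy - s.heel.y)
                                    for cx, cy in corners)
                    k += 1
                    continue
            errors[k] = np.hypot(p.x - s.heel.x, p.y - s.heel.y)
            k += 1
    return errors
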