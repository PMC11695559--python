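"""Loss, early stopping, learning-rate schedule and reproducibility."""

import numpy as np
import pytest

from gaitheel.data import LabelledSample
from gaitheel.errors import InvalidParameterError
from gaitheel.geometry import ImagePoint
from gaitheel.models import GaitHeelModel, ModelSpec
from gaitheel.pose import FootCrop
from gaitheel import nn
from gaitheel.synth import make_labelled_samples
from gaitheel.training import (
    TrainConfig,
    keypoint_errors,
    loss,
    simulate_early_stopping,
    train,
)


class TestLoss:
    def test_identical_inputs_zero(self):
        assert loss(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 0.0

    def test_normalized_point_example(self):
        assert loss(np.array([0.5, 0.5]),
                    np.array([0.5, 0.7])) == pytest.approx(0.02)

    def test_heatmap_example(self):
        a = np.zeros((2, 2))
        b = a.copy()
        b[0, 0] = 1.0
        assert loss(a, b) == pytest.approx(0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            loss(np.zeros(2), np.zeros(3))


class TestEarlyStopping:
    def test_injected_trace_stops_after_patience(self):
        """Validation losses [1.0, .9, .9, .9, .9, .9] with patience 4:
        stop after epoch 6, best epoch 2."""
        stopped, best = simulate_early_stopping(
            [1.0, 0.9, 0.9, 0.9, 0.9, 0.9], patience=4)
        assert (stopped, best) == (6, 2)

    def test_monotone_decrease_never_stops_early(self):
        trace = [1.0 / (i + 1) for i in range(10)]
        stopped, best = simulate_early_stopping(trace, patience=4)
        assert (stopped, best) == (10, 10)

    def test_strictly_lower_required_for_improvement(self):
        stopped, best = simulate_early_stopping(
            [1.0, 1.0, 1.0, 1.0, 1.0], patience=4)
        assert (stopped, best) == (5, 1)


class TestConfig:
    def test_patience_must_be_under_epochs(self):
        with pytest.raises(InvalidParameterError):
            TrainConfig(epochs=4, patience=4)

    def test_lr_decayed_by_factor_after_decay_epoch(self):
        cfg = TrainConfig(epochs=20, lr=0.01, lr_decay_epoch=10,
                          lr_decay_factor=0.1)
        assert cfg.lr_at(10) == pytest.approx(0.01)
        assert cfg.lr_at(11) == pytest.approx(0.001)
        assert cfg.lr_at(20) == pytest.approx(0.001)


def tiny_regression_model(seed=0) -> GaitHeelModel:
    """A minimal convnet with the regression-head contract, small enough
    for fast schedule/reproducibility checks on full-size crops."""
    rng = np.random.default_rng(seed)
    net = nn.Sequential(
        nn.Conv2d(3, 4, 3, stride=4, padding=1, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(4),
        nn.Conv2d(4, 8, 3, stride=2, padding=1, rng=rng),
        nn.ReLU(),
        nn.AdaptiveAvgPool2d((1, 1)),
        nn.Flatten(),
        nn.Linear(8, 2, rng=rng),
    )
    spec = ModelSpec("mobilenetv2", "regression")
    return GaitHeelModel(spec, net, output_grid=None)


@pytest.fixture(scope="module")
def tiny_dataset():
    samples = make_labelled_samples(10, 3, "side", rng_seed=2)
    return samples[:24], samples[24:]


class TestTrainLoop:
    def test_lr_schedule_recorded_in_history(self, tiny_dataset):
        tr, va = tiny_dataset
        cfg = TrainConfig(epochs=12, batch_size=8, lr=0.01,
                          lr_decay_epoch=10, patience=11, seed=0)
        _, hist = train(tiny_regression_model(), tr, va, cfg)
        if hist.stopped_epoch >= 11:
            assert hist.lr[9] == pytest.approx(0.01)
            assert hist.lr[10] == pytest.approx(0.001)
        assert all(l == pytest.approx(cfg.lr_at(i + 1))
                   for i, l in enumerate(hist.lr))

    def test_reproducible_under_fixed_seed(self, tiny_dataset):
        tr, va = tiny_dataset
        cfg = TrainConfig(epochs=3, batch_size=8, lr=1e-3, patience=2, seed=7)
        m1, h1 = train(tiny_regression_model(seed=1), tr, va, cfg)
        m2, h2 = train(tiny_regression_model(seed=1), tr, va, cfg)
        assert h1.train_loss == h2.train_loss
        for a, b in zip(m1.network.state_arrays(), m2.network.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_overfits_tiny_fixture(self, tiny_dataset):
        """Many passes over a handful of crops drive the train loss well
        below its starting value (sanity of the full update path)."""
        tr, va = tiny_dataset
        few = tr[:8]
        cfg = TrainConfig(epochs=60, batch_size=8, lr=0.02,
                          lr_decay_epoch=50, patience=59, seed=0)
        _, hist = train(tiny_regression_model(), few, few, cfg)
        assert hist.train_loss[-1] < 0.1 * hist.train_loss[0]

    def test_stops_within_budget_and_restores_best(self, tiny_dataset):
        tr, va = tiny_dataset
        cfg = TrainConfig(epochs=6, batch_size=8, lr=1e-3, patience=2, seed=0)
        model, hist = train(tiny_regression_model(), tr, va, cfg)
        assert hist.stopped_epoch <= cfg.epochs
        assert 1 <= hist.best_epoch <= hist.stopped_epoch
        assert len(hist.val_loss) == hist.stopped_epoch

    def test_empty_dataset_rejected(self, tiny_dataset):
        tr, va = tiny_dataset
        with pytest.raises(InvalidParameterError):
            train(tiny_regression_model(), [], va, TrainConfig(seed=0))

    def test_mixed_views_rejected(self, tiny_dataset):
        tr, va = tiny_dataset
        frontal = make_labelled_samples(2, 2, "frontal", rng_seed=0)
        with pytest.raises(InvalidParameterError):
            train(tiny_regression_model(), tr + frontal, va,
                  TrainConfig(seed=0))


def test_keypoint_errors_zero_for_perfect_stub(tiny_dataset):
    tr, _ = tiny_dataset
    model = tiny_regression_model()

    class Perfect:
        def forward(self, x, training=False):
            return np.array([[s.heel.x / 160, s.heel.y / 120]
                             for s in tr[: x.shape[0]]], dtype=np.float32)

    model.network = Perfect()
    errs = keypoint_errors(model, tr[:8])
    assert np.allclose(errs, 0.0, atol=1e-4)
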