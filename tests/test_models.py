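"""Model construction, parameter counts, heatmap rendering and decoding."""

import numpy as np
import pytest

from gaitheel.errors import (
    InvalidParameterError,
    InvalidSpecError,
    UndecodableHeatmapError,
)
from gaitheel.geometry import ImagePoint
from gaitheel.models import (
    GaitHeelModel,
    Heatmap,
    ModelSpec,
    build_model,
    count_parameters,
    decode_heatmap,
    predict_keypoint,
    render_target_heatmap,
)
from gaitheel import nn


class TestConstruction:
    def test_regression_head_parameter_count(self):
        head = nn.Linear(1000, 2)
        assert sum(p.size for p in head.parameters()) == 2002

    def test_unknown_backbone_rejected(self):
        with pytest.raises(InvalidSpecError):
            ModelSpec("alexnet", "regression")

    def test_unknown_head_rejected(self):
        with pytest.raises(InvalidSpecError):
            ModelSpec("vgg19", "softmax")

    def test_vgg19_regression_matches_published_size(self):
        model = build_model(ModelSpec("vgg19", "regression"))
        assert round(count_parameters(model) / 1e6, 1) == 143.7

    def test_mobilenetv2_regression_matches_published_size(self):
        model = build_model(ModelSpec("mobilenetv2", "regression"))
        assert round(count_parameters(model) / 1e6, 1) == 3.5

    def test_regression_forward_outputs_two_coordinates(self):
        model = build_model(ModelSpec("mobilenetv2", "regression"))
        x = np.zeros((1, 3, 120, 160), dtype=np.float32)
        assert model.forward(x).shape == (1, 2)

    @pytest.mark.parametrize("backbone", ["mobilenetv2", "resnext50", "vgg19"])
    def test_heatmap_output_near_input_resolution(self, backbone):
        """Single-channel output with height and width within a factor two
        of the 120x160 input."""
        model = build_model(ModelSpec(backbone, "heatmap"))
        x = np.zeros((1, 3, 120, 160), dtype=np.float32)
        out = model.forward(x)
        assert out.shape[:2] == (1, 1)
        gh, gw = out.shape[2:]
        assert 60 <= gh <= 240 and 80 <= gw <= 320
        assert (gh, gw) == model.output_grid


class TestTargetHeatmap:
    def test_peak_at_keypoint(self):
        hm = render_target_heatmap(ImagePoint(80, 60), (120, 160), sigma=3)
        r, c = np.unravel_index(np.argmax(hm.values), hm.values.shape)
        assert (c, r) == (80, 60)
        assert hm.values.max() == 1.0

    def test_gaussian_falloff_at_one_sigma(self):
        sigma = 4.0
        hm = render_target_heatmap(ImagePoint(40, 50), (120, 160), sigma)
        assert hm.values[50, 44] == pytest.approx(np.exp(-0.5))

    def test_tiny_sigma_concentrates_all_mass(self):
        hm = render_target_heatmap(ImagePoint(30, 30), (120, 160), sigma=0.1)
        assert hm.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            render_target_heatmap(ImagePoint(10, 10), (120, 160), sigma=0)


class TestDecode:
    def test_single_pixel_delta(self):
        values = np.zeros((40, 40))
        values[10, 10] = 1.0
        p = decode_heatmap(Heatmap(values))
        assert (p.x, p.y) == (10, 10)

    def test_render_decode_round_trip_subpixel(self):
        """Gaussian at a sub-pixel location decodes to within 0.1 px."""
        target = ImagePoint(45.25, 30.75)
        hm = render_target_heatmap(target, (120, 160), sigma=3)
        p = decode_heatmap(hm)
        assert abs(p.x - target.x) < 0.1 and abs(p.y - target.y) < 0.1

    @pytest.mark.parametrize("x,y", [(7, 7), (20, 100), (152, 40),
                                     (80.5, 59.5), (10.25, 110.5)])
    def test_round_trip_identity_for_interior_keypoints(self, x, y):
        hm = render_target_heatmap(ImagePoint(x, y), (120, 160), sigma=3)
        p = decode_heatmap(hm)
        assert abs(p.x - x) <= 0.1 and abs(p.y - y) <= 0.1

    def test_tie_break_weighted_mean(self):
        """Two equal maxima with no other mass: the window anchors on the
        smaller row-major index and the result is their weighted mean."""
        values = np.zeros((30, 30))
        values[5, 5] = 1.0
        values[5, 6] = 1.0
        p = decode_heatmap(Heatmap(values))
        assert (p.x, p.y) == (5.5, 5.0)

    def test_flip_equivariance_exact(self):
        # a unique global maximum: an exact half-pixel keypoint ties two
        # grid points and the tie then anchors asymmetrically under flips
        hm = render_target_heatmap(ImagePoint(41.25, 77.0), (120, 160), sigma=3)
        flipped = Heatmap(np.ascontiguousarray(hm.values[:, ::-1]),
                          hm.grid_to_input_scale)
        p = decode_heatmap(hm)
        q = decode_heatmap(flipped)
        w = hm.values.shape[1]
        assert q.x == pytest.approx((w - 1) - p.x, abs=1e-9)
        assert q.y == pytest.approx(p.y, abs=1e-9)

    def test_scale_maps_grid_to_input_coordinates(self):
        values = np.zeros((64, 80))
        values[32, 40] = 1.0
        p = decode_heatmap(Heatmap(values, grid_to_input_scale=(2.0, 1.875)))
        assert (p.x, p.y) == (80.0, 60.0)

    def test_negative_values_clamped_before_weighting(self):
        values = np.full((20, 20), -1.0)
        values[4, 4] = 2.0
        p = decode_heatmap(Heatmap(values))
        assert (p.x, p.y) == (4, 4)

    def test_all_nonpositive_heatmap_rejected(self):
        with pytest.raises(UndecodableHeatmapError):
            decode_heatmap(Heatmap(np.full((10, 10), -0.5)))


class TestPredict:
    def test_regression_denormalization(self):
        """A regression model whose network emits (0.5, 0.5) predicts the
        crop center (80, 60); (0, 0) maps to the origin."""
        model = build_model(ModelSpec("mobilenetv2", "regression"))

        class Stub:
            def __init__(self, vec):
                self.vec = np.asarray(vec, dtype=np.float32)

            def forward(self, x, training=False):
                return np.tile(self.vec, (x.shape[0], 1))

        crop = np.zeros((120, 160, 3), dtype=np.uint8)
        model.network = Stub([0.5, 0.5])
        assert predict_keypoint(model, crop) == ImagePoint(80.0, 60.0)
        model.network = Stub([0.0, 0.0])
        assert predict_keypoint(model, crop) == ImagePoint(0.0, 0.0)

    def test_heatmap_prediction_decodes_network_response(self):
        model = build_model(ModelSpec("mobilenetv2", "heatmap"))
        gh, gw = model.output_grid

        class Stub:
            def forward(self, x, training=False):
                out = np.zeros((x.shape[0], 1, gh, gw), dtype=np.float32)
                out[:, 0, 64, 40] = 1.0
                return out

        model.network = Stub()
        p = predict_keypoint(model, np.zeros((120, 160, 3), dtype=np.uint8))
        sx, sy = model.grid_to_input_scale
        assert (p.x, p.y) == (40 * sx, 64 * sy)

    def test_wrong_crop_size_rejected(self):
        model = build_model(ModelSpec("mobilenetv2", "regression"))
        with pytest.raises(InvalidParameterError):
            predict_keypoint(model, np.zeros((100, 100, 3), dtype=np.uint8))


def test_checkpoint_round_trip(tmp_path):
    from gaitheel.models import load_checkpoint, save_checkpoint
    model = build_model(ModelSpec("mobilenetv2", "heatmap"), rng_seed=5)
    x = np.random.default_rng(0).standard_normal((1, 3, 120, 160)).astype(np.float32)
    ref = model.forward(x)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model)
    loaded = load_checkpoint(path)
    assert loaded.spec == model.spec
    np.testing.assert_array_equal(loaded.forward(x), ref)
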