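"""Floor-axis errors, box-plot statistics and step parameters."""

import itertools

import numpy as np
import pytest

from gaitheel.errors import InvalidParameterError
from gaitheel.evaluation import (
    floor_axis_error,
    step_parameters,
    summarize_errors,
)
from gaitheel.events import Trajectory, detect_heel_strikes, heel_to_heel_distance
from gaitheel.geometry import (
    FloorPoint,
    Homography,
    ImagePoint,
    project_to_floor,
)


def brute_force_summary(values):
    """Independent box-plot oracle: explicit rank interpolation for the
    quartiles, explicit fence comparison for the outliers."""
    xs = sorted(values)
    n = len(xs)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])

    q1, med, q3 = quantile(0.25), quantile(0.5), quantile(0.75)
    iqr = q3 - q1
    outliers = [v for v in xs if v > q3 + 1.5 * iqr or v < q1 - 1.5 * iqr]
    return dict(min=xs[0], max=xs[-1], median=med, q1=q1, q3=q3, iqr=iqr,
                outlier_fraction=len(outliers) / n)


class TestSummarize:
    def test_worked_example_with_one_outlier(self):
        s = summarize_errors([1, 2, 3, 4, 100])
        assert s.median == 3 and s.q1 == 2 and s.q3 == 4 and s.iqr == 2
        assert s.outlier_fraction == pytest.approx(0.2)
        assert s.min == 1 and s.max == 100

    def test_singleton(self):
        s = summarize_errors([5.0])
        assert (s.min, s.max, s.median, s.q1, s.q3) == (5, 5, 5, 5, 5)
        assert s.iqr == 0 and s.outlier_fraction == 0

    def test_constant_list(self):
        s = summarize_errors([2.5] * 9)
        assert s.iqr == 0 and s.outlier_fraction == 0

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            summarize_errors([])

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = summarize_errors(rng.exponential(2.0, size=rng.integers(1, 40)))
            assert s.min <= s.q1 <= s.median <= s.q3 <= s.max
            assert s.iqr == pytest.approx(s.q3 - s.q1)

    def test_matches_bruteforce_on_exhaustive_small_lists(self):
        """Oracle equivalence on every integer list of length <= 3 with
        values in [0, 10], plus seeded longer lists up to length 8."""
        cases = []
        for n in (1, 2, 3):
            cases.extend(itertools.product(range(0, 11), repeat=n))
        rng = np.random.default_rng(42)
        for n in (4, 5, 6, 7, 8):
            for _ in range(200):
                cases.append(tuple(rng.integers(0, 11, size=n)))
        for values in cases:
            got = summarize_errors(list(values))
            want = brute_force_summary(values)
            for key, w in want.items():
                assert getattr(got, key) == pytest.approx(w), (values, key)


class TestFloorAxisError:
    def test_identity_side_view_axis_difference(self):
        e = floor_axis_error(ImagePoint(12, 5), ImagePoint(10, 5),
                             ImagePoint(0, 0), Homography.identity(), "side")
        assert e == 2.0

    def test_perfect_prediction_zero(self):
        e = floor_axis_error(ImagePoint(10, 5), ImagePoint(10, 5),
                             ImagePoint(3, 4), Homography.identity(), "side")
        assert e == 0.0

    def test_scaling_homography_doubles_error(self):
        h = Homography(np.diag([2.0, 2.0, 1.0]))
        e = floor_axis_error(ImagePoint(12, 5), ImagePoint(10, 5),
                             ImagePoint(0, 0), h, "side")
        assert e == 4.0

    def test_frontal_uses_floor_y(self):
        e = floor_axis_error(ImagePoint(12, 9), ImagePoint(10, 5),
                             ImagePoint(0, 0), Homography.identity(), "frontal")
        assert e == 4.0

    def test_crop_origin_applied_before_projection(self, known_homography):
        pred, label = ImagePoint(12, 5), ImagePoint(10, 5)
        origin = ImagePoint(100, 200)
        e = floor_axis_error(pred, label, origin, known_homography, "side")
        a = project_to_floor(known_homography, ImagePoint(112, 205))
        b = project_to_floor(known_homography, ImagePoint(110, 205))
        assert e == pytest.approx(abs(a.x - b.x))

    def test_invariant_to_pure_floor_y_translation_for_side_view(self):
        h = Homography(np.array([[1.1, 0.02, -3.0],
                                 [0.01, 0.95, 7.0],
                                 [1e-4, 2e-5, 1.0]]))
        shift = np.array([[1.0, 0, 0], [0, 1.0, 25.0], [0, 0, 1.0]])
        h_shifted = Homography(shift @ h.h)
        args = (ImagePoint(40, 30), ImagePoint(42, 33), ImagePoint(10, 20))
        assert floor_axis_error(*args, h, "side") == pytest.approx(
            floor_axis_error(*args, h_shifted, "side"))


class TestStepParameters:
    def test_coordinate_differences(self):
        p = [FloorPoint(0, 0), FloorPoint(60, 10), FloorPoint(120, 0)]
        sp = step_parameters(p)
        assert sp.step_lengths == (60, 60)
        assert sp.step_widths == (10, 10)

    def test_identical_points_degenerate(self):
        sp = step_parameters([FloorPoint(5, 5), FloorPoint(5, 5)])
        assert sp.step_lengths == (0,) and sp.step_widths == (0,)

    def test_single_point_rejected(self):
        with pytest.raises(InvalidParameterError):
            step_parameters([FloorPoint(0, 0)])


class TestEndToEndNoiseless:
    def test_truth_keypoints_give_zero_error_and_planted_steps(
            self, noiseless_gait, side_camera):
        """Full pipeline on noiseless synthetic gait with ground-truth heel
        keypoints substituted for network predictions: detected strikes are
        the planted ones, floor-axis errors are zero, and step parameters
        equal the planted 60 cm / 10 cm."""
        frames, truth = noiseless_gait
        left = Trajectory.from_pose_frames(frames, "left_heel")
        right = Trajectory.from_pose_frames(frames, "right_heel")
        strikes = detect_heel_strikes(heel_to_heel_distance(left, right))
        assert strikes == list(truth.heel_strike_frames)

        contacts = []
        for i, s in enumerate(strikes):
            side = "left" if i % 2 == 0 else "right"
            heel = frames[s].keypoint(f"{side}_heel")
            err = floor_axis_error(heel, heel, ImagePoint(0, 0),
                                   side_camera, "side")
            assert err == 0.0
            contacts.append(project_to_floor(side_camera, heel))
        sp = step_parameters(contacts)
        assert np.allclose(sp.step_lengths, truth.step_length_world, atol=1e-6)
        assert np.allclose(sp.step_widths, truth.step_width_world, atol=1e-6)
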