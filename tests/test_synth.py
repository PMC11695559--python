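"""Synthetic generators: determinism and geometric ground-truth guarantees."""

import numpy as np
import pytest

from gaitheel.errors import InvalidParameterError
from gaitheel.events import Trajectory, heel_to_heel_distance
from gaitheel.geometry import ImagePoint, project_to_floor
from gaitheel.synth import (
    CROP_MARGIN_X,
    CROP_MARGIN_Y,
    FootSceneParams,
    GaitScenarioParams,
    make_labelled_samples,
    random_foot_params,
    render_foot_frame,
    render_foot_image,
    strike_floor_positions,
    synth_calibration_scene,
    synth_gait_trajectories,
)


class TestFootRendering:
    def test_deterministic_under_fixed_seed(self, foot_params_side):
        img1, heel1 = render_foot_image(foot_params_side, rng_seed=7)
        img2, heel2 = render_foot_image(foot_params_side, rng_seed=7)
        assert heel1 == heel2
        np.testing.assert_array_equal(img1, img2)

    def test_different_seeds_vary(self, foot_params_side):
        img1, _ = render_foot_image(foot_params_side, rng_seed=1)
        img2, _ = render_foot_image(foot_params_side, rng_seed=2)
        assert (img1 != img2).any()

    def test_heel_passthrough_and_dimensions(self, foot_params_side):
        img, heel = render_foot_image(foot_params_side, rng_seed=7)
        assert img.shape[:2] == (120, 160)
        assert heel == ImagePoint(30, 100)

    @pytest.mark.parametrize("view", ["side", "frontal"])
    @pytest.mark.parametrize("seed", [0, 5, 23, 91])
    def test_contact_pixel_matches_heel(self, view, seed):
        """The silhouette's most posterior / most lateral pixel on the floor
        line is within 1 px of the declared heel keypoint."""
        rng = np.random.default_rng(seed)
        params = random_foot_params(view, rng)
        scene = render_foot_frame(params, rng_seed=seed + 100)
        row = int(params.floor_row) + CROP_MARGIN_Y
        cols = np.where(scene.mask[row])[0]
        assert cols.size > 0, "no silhouette pixel on the floor line"
        assert abs(cols.min() - scene.heel_frame.x) <= 1.0

    def test_heel_outside_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            FootSceneParams(foot_length=80, foot_height=30,
                            heel_position=ImagePoint(200, 100),
                            floor_row=100, view="side")

    def test_heel_off_floor_line_rejected(self):
        with pytest.raises(InvalidParameterError):
            FootSceneParams(foot_length=80, foot_height=30,
                            heel_position=ImagePoint(30, 90),
                            floor_row=100, view="side")

    def test_labelled_samples_tagged_by_subject(self):
        samples = make_labelled_samples(3, 2, "side", rng_seed=0)
        assert len(samples) == 6
        assert len({s.crop.subject_id for s in samples}) == 3
        for s in samples:
            assert s.crop.pixels.shape[:2] == (120, 160)


class TestGaitScenarios:
    def test_distance_maxima_exactly_at_planted_strikes(self, noiseless_gait):
        frames, truth = noiseless_gait
        left = Trajectory.from_pose_frames(frames, "left_heel")
        right = Trajectory.from_pose_frames(frames, "right_heel")
        series = heel_to_heel_distance(left, right)
        v = series.values
        for s in truth.heel_strike_frames:
            assert v[s] > v[s - 1] and v[s] > v[s + 1], f"no strict max at {s}"

    def test_strike_positions_project_to_planted_floor_points(
            self, noiseless_gait, side_camera):
        """Heel image positions at strike frames, projected to the floor,
        land on the planted grid: consecutive strikes 60 cm apart along x,
        alternating +-5 cm in y."""
        frames, truth = noiseless_gait
        planted = strike_floor_positions(truth)
        for i, s in enumerate(truth.heel_strike_frames):
            side = "left" if i % 2 == 0 else "right"
            heel = frames[s].keypoint(f"{side}_heel")
            fp = project_to_floor(side_camera, heel)
            assert abs(fp.x - planted[i].x) < 1e-6
            assert abs(fp.y - planted[i].y) < 1e-6
        xs = [p.x for p in planted]
        assert np.allclose(np.diff(xs), truth.step_length_world)

    def test_deterministic_under_fixed_seed(self, side_camera):
        params = GaitScenarioParams.regular(n_frames=80, step_period=16,
                                            first_strike=20, noise_sd=1.0)
        f1, _ = synth_gait_trajectories(params, side_camera, rng_seed=5)
        f2, _ = synth_gait_trajectories(params, side_camera, rng_seed=5)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.points, b.points)

    def test_short_scenario_rejected(self):
        with pytest.raises(InvalidParameterError):
            GaitScenarioParams(n_frames=20, step_period=15,
                               heel_strike_frames=(5, 18))

    def test_unsorted_strikes_rejected(self):
        with pytest.raises(InvalidParameterError):
            GaitScenarioParams(n_frames=100, step_period=10,
                               heel_strike_frames=(30, 20))


class TestCalibrationScenes:
    def test_identity_scene_pairs_coincide(self):
        from gaitheel.geometry import Homography
        pairs = synth_calibration_scene(Homography.identity(), 5, 0.0,
                                        rng_seed=2)
        for ip, fp in pairs:
            assert abs(ip.x - fp.x) < 1e-9 and abs(ip.y - fp.y) < 1e-9

    def test_noiseless_pairs_satisfy_projective_relation(self, known_homography):
        pairs = synth_calibration_scene(known_homography, 6, 0.0, rng_seed=4)
        for ip, fp in pairs:
            proj = project_to_floor(known_homography, ip)
            assert np.hypot(proj.x - fp.x, proj.y - fp.y) < 1e-9

    def test_fewer_than_four_points_rejected(self, known_homography):
        with pytest.raises(InvalidParameterError):
            synth_calibration_scene(known_homography, 3, 0.0, rng_seed=0)

    def test_deterministic(self, known_homography):
        a = synth_calibration_scene(known_homography, 6, 0.5, rng_seed=9)
        b = synth_calibration_scene(known_homography, 6, 0.5, rng_seed=9)
        assert a == b
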