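import numpy as np
import pytest

from gaitheel.geometry import FloorPoint, Homography, ImagePoint
from gaitheel.synth import (
    FootSceneParams,
    GaitScenarioParams,
    example_homography,
    random_foot_params,
    synth_gait_trajectories,
)


@pytest.fixture(scope="session")
def side_camera() -> Homography:
    """A plausible side-view image->floor homography."""
    return example_homography()


@pytest.fixture(scope="session")
def known_homography() -> Homography:
    """A nonsingular, clearly non-trivial projective map."""
    return Homography(np.array([
        [1.2, 0.1, -30.0],
        [-0.05, 0.9, 12.0],
        [1e-4, -2e-4, 1.0],
    ]))


@pytest.fixture
def foot_params_side() -> FootSceneParams:
    return FootSceneParams(foot_length=90, foot_height=32,
                           heel_position=ImagePoint(30, 100), floor_row=100,
                           view="side")


@pytest.fixture(scope="session")
def noiseless_gait(side_camera):
    params = GaitScenarioParams(
        n_frames=100, step_period=25, heel_strike_frames=(20, 45, 70),
        step_length_world=60.0, step_width_world=10.0, noise_sd=0.0)
    frames, truth = synth_gait_trajectories(params, side_camera, rng_seed=7)
    return frames, truth
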