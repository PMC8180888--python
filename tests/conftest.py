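import numpy as np
import pytest

from snntraj.scenes import SceneConfig, LaunchParams, simulate_trajectory, render_frames
from snntraj.frontend import FrontendConfig, encode_sequence, tuned_config


@pytest.fixture(scope="session")
def small_scene() -> SceneConfig:
    """A 48x40 px, 60 fps scene used by most integration-style tests."""
    return SceneConfig(width=48, height=40, fps=60.0, ball_radius=2,
                       pixel_pitch=0.0575, gravity=9.81,
                       reception_x_left=4, reception_x_right=43, seed=7)


@pytest.fixture(scope="session")
def sample_throw(small_scene):
    truth = simulate_trajectory(small_scene,
                                LaunchParams(7, 30, 4.0, 50.0))
    frames = render_frames(truth, small_scene)
    return truth, frames


@pytest.fixture(scope="session")
def sample_events(small_scene, sample_throw):
    truth, frames = sample_throw
    fc = tuned_config(frames, FrontendConfig(fps=small_scene.fps), 0.003)
    return encode_sequence(frames, fc), fc
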