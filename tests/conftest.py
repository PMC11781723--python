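import numpy as np
import pytest
from hypothesis import settings

from vbpe import anthropometry as anthro
from vbpe import synthetic as syn

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def skin_video():
    """A full-resolution noiseless pulsating-skin clip with a 2-sample delay.

    16 s at 60 fps: long enough for >5 beat pairs, short enough to build
    once per session.
    """
    spec = syn.SignalSpec(
        fs=60.0, duration_s=16.0, transit_delay_s=2 / 60, noise_sd=0.0, seed=7
    )
    return spec, syn.generate_skin_video(spec)


SMALL_LAYOUT = syn.VideoLayout(
    width=160,
    height=120,
    face_rect=(20, 16, 70, 48),
    hand_rect=(96, 24, 146, 84),
)


@pytest.fixture(scope="session")
def small_video():
    """A low-resolution clip (below the strict minimum) for fast IO tests."""
    spec = syn.SignalSpec(
        fs=60.0, duration_s=12.0, transit_delay_s=2 / 60, noise_sd=0.0, seed=3
    )
    return spec, syn.generate_skin_video(spec, layout=SMALL_LAYOUT)


@pytest.fixture()
def demographics():
    return anthro.Demographics(
        subject_id="t01", height_cm=160.0, weight_kg=64.0, age_years=40.0
    )


@pytest.fixture()
def pose_fixture():
    pose, truth = syn.generate_pose_fixture(
        height_cm=160.0, camera_scale_p=5.0, dist_face_cm=40.0, dist_hand_cm=66.0
    )
    return pose, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
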