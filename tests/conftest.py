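import dataclasses

import numpy as np
import pytest

from fees_xai.synthetic import SceneConfig, generate_video


@pytest.fixture(scope="session")
def small_scene_config() -> SceneConfig:
    """A short scene with frequent bolus events, for fast pipeline tests."""
    return SceneConfig(
        image_size=(128, 128),
        n_frames=60,
        bolus_event_rate=8.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scene_config):
    return generate_video(small_scene_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
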