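import numpy as np
import pytest

from tirftrack import SceneConfig, straight_path


@pytest.fixture
def rng():
    return np.random.default_rng(20230626)


@pytest.fixture
def small_config():
    """A small, fast scene: one short microtubule, default camera model."""
    return SceneConfig(n_frames=50, image_size=(48, 96), seed=11)


@pytest.fixture
def horizontal_path(small_config):
    H, W = small_config.image_size
    return straight_path(H / 2, 8, W - 9, pixel_size=small_config.pixel_size)
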