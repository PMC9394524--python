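import numpy as np
import pytest
from hypothesis import settings

from polarcap import SceneConfig, render_scene

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_scene():
    """One-frame zero-noise scene with a 1 µm planted offset."""
    cfg = SceneConfig(offset_um=1.0, noise_sigma=0.0, n_frames=1)
    stack, truth = render_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise scene (SNR 5), 3 frames."""
    cfg = SceneConfig(offset_um=1.0, n_frames=3, seed=7)
    stack, truth = render_scene(cfg)
    return cfg, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
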