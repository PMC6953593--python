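import numpy as np
import pytest

from histocyto import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A modest default-noise scene shared by read-only tests."""
    cfg = SceneConfig(seed=11, n_nuclei=80, image_size_px=(512, 512))
    image, truth = generate_scene(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    """Noise- and gradient-free scene: footprints are exact."""
    cfg = SceneConfig(
        seed=17,
        n_nuclei=60,
        image_size_px=(512, 512),
        noise_sd=0.0,
        background_gradient_amplitude=0.0,
    )
    image, truth = generate_scene(cfg)
    return cfg, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
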