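import dataclasses

import numpy as np
import pytest

from osteolcn import SceneConfig, degrade_to_aged, generate_scene


def noise_free(config: SceneConfig) -> SceneConfig:
    return dataclasses.replace(config, noise_sd=0.0, illumination_gradient=0.0)


def tiny_config(seed: int) -> SceneConfig:
    """64x64 two-soma scenes for desk-scale training runs."""
    return SceneConfig(
        image_height=64, image_width=64, n_osteocytes=2,
        osteocyte_axes_range=(4.0, 7.0), connection_radius_px=60.0,
        connection_length_scale_px=200.0, connection_probability=1.0,
        dead_end_rate=1.0, stub_length_range=(6.0, 12.0),
        noise_sd=4.0, illumination_gradient=0.1, seed=seed,
    )


@pytest.fixture(scope="session")
def noise_free_scenes_50():
    """Fifty noise-free default scenes: the planted-recovery test bed."""
    return [generate_scene(noise_free(SceneConfig(seed=s))) for s in range(50)]


@pytest.fixture(scope="session")
def young_scenes_30():
    return [generate_scene(SceneConfig(seed=s)) for s in range(30)]


@pytest.fixture(scope="session")
def aged_scenes_30():
    aged = degrade_to_aged(SceneConfig(), severity=1.0)
    return [generate_scene(dataclasses.replace(aged, seed=1000 + s)) for s in range(30)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
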