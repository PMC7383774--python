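import numpy as np
import pytest

from rvtrack.phantom import PhantomConfig, generate_case


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Small, fast phantom: 64 px, 8 frames, 0.8 cm lateral excursion."""
    return PhantomConfig(
        image_size=64,
        pixel_spacing=0.1,
        n_frames=8,
        lateral_amplitude=0.8,
        septal_amplitude=0.6,
        label_radius=2,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_case(tiny_config):
    return generate_case(tiny_config, case_id="tiny")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
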