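import numpy as np
import pytest

from qlisa.device import BeadSpec, ChannelProfile
from qlisa.simulate import SimConfig, _default_crossover


@pytest.fixture
def two_plex_profile() -> ChannelProfile:
    """The 2 cm x 3 mm channel used for the two-bead multiplex
    (inlet 7.583 µm, outlet 2.077 µm)."""
    return ChannelProfile(20000.0, 3000.0, 7.583, 2.077)


@pytest.fixture
def small_config() -> SimConfig:
    """A reduced-size single-analyte configuration for fast image tests."""
    return SimConfig(
        seed=123,
        image_shape=(160, 200),
        bead_specs=(BeadSpec("GFAP", 2.8, 0.03, "Qdot585"),),
        channels=("Qdot585",),
        crossover=_default_crossover(("Qdot585",)),
        autofluorescence={},
        beads_per_fov=25,
        n_fov=2,
        debris_per_fov=5.0,
    )


@pytest.fixture
def clean_small_config(small_config) -> SimConfig:
    """Same geometry but a fully deterministic, noise-free render."""
    return SimConfig.from_dict(
        {
            **small_config.to_dict(),
            "epi_noise_sd": 0.0,
            "fluor_noise_sd": 0.0,
            "bead_brightness_cv": 0.0,
            "fov_effect_cv": 0.0,
            "replicate_effect_cv": 0.0,
            "debris_per_fov": 0.0,
            "illumination": {},
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
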