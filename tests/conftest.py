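import numpy as np
import pytest

from ctai.synthetic_data import ScenarioConfig, generate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact distorted paired-instrument scenario shared across tests."""
    cfg = ScenarioConfig(n_cal=40, n_test=12, p=80, seed=11)
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def clean_scenario():
    """Noise-free, distortion-free scenario: slave physics equals master."""
    cfg = ScenarioConfig(
        n_cal=40,
        n_test=12,
        p=80,
        seed=5,
        gain_amplitude=0.0,
        offset_amplitude=0.0,
        wavelength_shift=0.0,
        scatter_sd=0.0,
        noise_sd_master=0.0,
        noise_sd_slave=0.0,
    )
    return generate_scenario(cfg)
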