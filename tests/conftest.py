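import numpy as np
import pytest

from hsitex import GeneratorConfig, generate_dataset
from hsitex.preprocessing import sg_smooth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """One-region low-noise linear dataset shared across model tests."""
    cfg = GeneratorConfig(n_samples=120, n_bands=150, regions=("dorsal",),
                          noise_sd_texture=0.05, nonlinearity=0.0, seed=42)
    spectra, table, truth = generate_dataset(cfg)
    return spectra["dorsal"], table, truth


@pytest.fixture(scope="session")
def smoothed_dataset(small_dataset):
    sm, table, truth = small_dataset
    return sg_smooth(sm), table, truth
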