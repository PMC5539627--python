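import numpy as np
import pytest

from nircal import SyntheticConfig, simulate_dataset
from nircal.io import average_replicates


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-sample triplicate dataset with the default study conditions."""
    cfg = SyntheticConfig(n_samples=40)
    spectra, reference, truth = simulate_dataset(cfg, seed=11)
    return spectra, reference, truth


@pytest.fixture(scope="session")
def averaged_small_dataset(small_dataset):
    spectra, reference, truth = small_dataset
    return average_replicates(spectra), reference, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
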