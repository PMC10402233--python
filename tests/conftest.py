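import numpy as np
import pytest

from phossum.geometry import AxonMapModel
from phossum.synthetic import GeneratorConfig, sample_dataset


@pytest.fixture(scope="session")
def axon_model():
    """Shared axon map (the seed fan is expensive to build)."""
    return AxonMapModel()


@pytest.fixture(scope="session")
def small_dataset(axon_model):
    """A small but complete synthetic dataset used across test modules."""
    cfg = GeneratorConfig(n_electrodes=6, trials_per_stim=3, n_pairs=6)
    return sample_dataset(cfg, seed=11, model=axon_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
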