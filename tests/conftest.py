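import numpy as np
import pytest

from planktonscape.synthetic_data import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def small_neutral_dataset():
    """A compact neutral survey shared by read-only tests."""
    params = SimulationParams(
        assembly_mode="neutral", seed=11, n_otus=300, reads_per_sample=3000
    )
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def small_deterministic_dataset():
    """A compact niche-filtered survey shared by read-only tests."""
    params = SimulationParams(
        assembly_mode="deterministic", seed=11, n_otus=300, reads_per_sample=3000
    )
    return simulate_dataset(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
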