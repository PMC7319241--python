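import numpy as np
import pytest

from oeflab.microcosm import MicrocosmConfig, generate_experiment


@pytest.fixture(scope="session")
def experiment_table():
    """One default synthetic experiment (30 microcosms, seed 0)."""
    return generate_experiment(seed=0)


@pytest.fixture(scope="session")
def experiment_batch():
    """Twenty replicate experiments (seeds 0..19), shared across tests."""
    return [generate_experiment(seed=s) for s in range(20)]


@pytest.fixture(scope="session")
def noise_free_config():
    return MicrocosmConfig(sigma_env=0.0, sigma_obs=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240517)
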