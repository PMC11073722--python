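import numpy as np
import pytest

from fawphen import GeneratorConfig, generate_life_table, reference_model


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def synthetic_obs():
    """One seeded synthetic life-table experiment at the default design."""
    return generate_life_table(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_obs():
    """A reduced design for fast end-to-end tests."""
    return generate_life_table(GeneratorConfig(seed=7, n_per_temperature=40, n_pairs=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
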