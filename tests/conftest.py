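import numpy as np
import pytest

from lairelease.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """120-formulation synthetic study at default conditions."""
    return generate_dataset(120, seed=1234)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Noise-free study for exact label/driver checks."""
    return generate_dataset(200, seed=77, config=SyntheticConfig(noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
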