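import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ucekit.synth import SimConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ds():
    """Small synthetic dataset shared by unit tests (~65 loci, 20 taxa)."""
    return generate_dataset(SimConfig(seed=7, n_proteins=60))


@pytest.fixture(scope="session")
def default_ds():
    """One dataset at the reference study conditions (~300 loci)."""
    return generate_dataset(SimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
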