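import pytest
from hypothesis import HealthCheck, settings

from tdel.encoding import design_scheme
from tdel.simulate import synthetic_library

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

SAMPLES = ["pre", "target", "no_target", "no_ligand"]


@pytest.fixture(scope="session")
def small_scheme():
    """A complete desk-scale encoding design shared across tests."""
    return design_scheme({"A": 6, "B": 4, "C": 6}, SAMPLES, seed=11)


@pytest.fixture(scope="session")
def small_library(small_scheme):
    return synthetic_library(small_scheme, seed=3)
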