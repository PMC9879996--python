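import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mbescope import load_registry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
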