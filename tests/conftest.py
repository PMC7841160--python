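import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=30,
                          deadline=None)
settings.load_profile("ci")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def rate0_bundle():
    """Small zero-divergence clade shared by integration tests."""
    from denovobirth.config import SimConfig
    from denovobirth.simulate import simulate_bundle
    cfg = SimConfig(rng_seed=11, substitution_rate=0.0, indel_rate=0.0)
    return simulate_bundle(cfg)
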