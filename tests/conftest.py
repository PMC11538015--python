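import numpy as np
import pytest

from gosel.synthetic import SyntheticSpec, generate_planted_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One planted dataset at the default study conditions."""
    return generate_planted_dataset(SyntheticSpec(seed=3))


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast spec for smoke-level training tests."""
    return SyntheticSpec(n=240, d_f=16, k_terms=6, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_planted_dataset(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
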