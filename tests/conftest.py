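import numpy as np
import pytest

from dimerfeat import FixtureSpec, build_fixture, build_random_dimer


@pytest.fixture(scope="session")
def small_dimer():
    """A compact random dimer with a real interface."""
    return build_random_dimer(8, separation=5.0, seed=11)


@pytest.fixture(scope="session")
def separated_dimer():
    """Two chains far beyond every interaction cutoff."""
    return build_random_dimer(5, separation=100.0, seed=7)


@pytest.fixture(scope="session")
def tripeptide():
    return build_fixture(FixtureSpec("extended_tripeptide"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
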