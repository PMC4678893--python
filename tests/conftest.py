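import numpy as np
import pytest

from hemiflow import build_paradigm, build_parcellation, demo_network


@pytest.fixture(scope="session")
def paradigm80():
    """The standard 80-volume paradigm: 4+4 blocks of 30 s at TR 3 s."""
    return build_paradigm(4, 30, 3, 5)


@pytest.fixture(scope="session")
def paradigm240():
    """A longer run (12+12 blocks) for connectivity experiments."""
    return build_paradigm(12, 30, 3, 0)


@pytest.fixture(scope="session")
def small_parcellation():
    """Six mirrored block regions on a 16 x 18 x 8 lattice."""
    return build_parcellation(
        ["A_L", "B_L", "C_L", "A_R", "B_R", "C_R"], shape=(16, 18, 8)
    )


@pytest.fixture(scope="session")
def network8():
    return demo_network()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
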