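import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sahelix.io import load_fixture_sequences
from sahelix.helixgeom import build_ideal_helix


@pytest.fixture(scope="session")
def constructs():
    """Packaged construct sequences (EK3 ... M6R)."""
    return load_fixture_sequences()


@pytest.fixture(scope="session")
def ala12():
    return build_ideal_helix("A" * 12)


@pytest.fixture(scope="session")
def ek3_helix(constructs):
    return build_ideal_helix(constructs["EK3"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
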