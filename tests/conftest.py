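import numpy as np
import pytest

from cytodmri.synthetic import make_protocol, study_protocol


@pytest.fixture(scope="session")
def full_protocol():
    return study_protocol()


@pytest.fixture(scope="session")
def small_protocol():
    """Cheap 3-shell protocol for fit tests that do not need 191 measurements."""
    return make_protocol(4, 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
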