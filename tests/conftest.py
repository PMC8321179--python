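import numpy as np
import pytest

from daltonise import fixture_suite, make_observer, suite_specs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rg_dichromat():
    return make_observer("rg", 1.0)


@pytest.fixture
def by_dichromat():
    return make_observer("by", 1.0)


@pytest.fixture(scope="session")
def small_suite():
    """Small deterministic image suite shared across slow tests."""
    return fixture_suite(14, 0, (128, 128))


@pytest.fixture(scope="session")
def small_suite_specs():
    return suite_specs(14, 0, (128, 128))
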