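import numpy as np
import pytest

from agephantom.phantom_model import generate_fixture_phantom


@pytest.fixture(scope="session")
def fixture_pair():
    """The deterministic synthetic phantom and growth table (seed 7)."""
    return generate_fixture_phantom(seed=7)


@pytest.fixture(scope="session")
def phantom(fixture_pair):
    return fixture_pair[0]


@pytest.fixture(scope="session")
def growth_table(fixture_pair):
    return fixture_pair[1]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
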