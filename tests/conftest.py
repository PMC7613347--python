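import numpy as np
import pytest

from prosailgpr.leaf import default_absorption_table
from prosailgpr.synthetic import coefficient_fixture, generate_soil_library


@pytest.fixture(scope="session")
def table():
    """Package default (synthetic) leaf optical constants."""
    return default_absorption_table()


@pytest.fixture(scope="session")
def fixture_table():
    """Independent minimal coefficient table."""
    return coefficient_fixture()


@pytest.fixture(scope="session")
def soil_library():
    return generate_soil_library(12, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
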