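import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from censtab import (
    load_reference_expected,
    load_reference_filled,
    load_wine_table,
)


@pytest.fixture(scope="session")
def wine_table():
    return load_wine_table()


@pytest.fixture(scope="session")
def reference_filled():
    """Published converged observed/estimated matrix (5x3)."""
    return load_reference_filled().values


@pytest.fixture(scope="session")
def reference_expected():
    """Published expected matrix, margin-consistent version (5x3)."""
    return load_reference_expected().values


@pytest.fixture(scope="session")
def wine_years():
    return np.array([1995.0, 2000.0, 2002.0, 2003.0, 2005.0])
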