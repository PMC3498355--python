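import numpy as np
import pytest

from halokit.compounds import load_table1
from halokit.qsar import build_matrix


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def matrix_all(table1):
    """10-compound matrix, censored parent held at its activity bound."""
    return build_matrix(table1, censor="bound")


@pytest.fixture(scope="session")
def matrix_active(table1):
    """9-compound matrix with the censored parent excluded."""
    return build_matrix(table1, censor="exclude")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
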