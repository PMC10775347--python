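import numpy as np
import pytest

from vistamrf.dictionary import DictionaryGrid, build_dictionary, compute_basis
from vistamrf.protocol import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def tiny_grid():
    """A few-atom grid for fast matching/basis tests."""
    return DictionaryGrid(
        t1_values=np.array([120.0, 500.0, 750.0, 1300.0, 2000.0]),
        t2_values=np.array([20.0, 60.0, 75.0, 110.0]),
        b1_values=np.array([0.8, 0.9, 1.0, 1.1]),
    )


@pytest.fixture(scope="session")
def tiny_dictionary(tiny_grid, protocol):
    return build_dictionary(tiny_grid, protocol)


@pytest.fixture(scope="session")
def tiny_basis(tiny_dictionary):
    return compute_basis(tiny_dictionary, 8)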