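import numpy as np
import pytest

from melsum import spectral as sp
from melsum import substitution as sub


@pytest.fixture(scope="session")
def grid():
    return sp.default_grid()


@pytest.fixture(scope="session")
def primaries(grid):
    return sp.default_primary_basis(grid)


@pytest.fixture(scope="session")
def receptors(grid):
    return sp.build_receptor_set(grid)


@pytest.fixture(scope="session")
def working_point():
    """Instrument working point: gamut-maximising background at 200 Td."""
    return sub.study_background(200.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220603)
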