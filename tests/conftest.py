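import numpy as np
import pytest

from tlbhe import Params, load_fixture
from tlbhe.estimation import fit_ml

PARAM_GRID = [Params(pi, a) for pi in (0.1, 0.5, 1.0, 5.0) for a in (0.3, 1.0, 2.0, 10.0)]


@pytest.fixture(scope="session")
def param_grid():
    return PARAM_GRID


@pytest.fixture(scope="session")
def glass():
    return load_fixture("glass_fibers")


@pytest.fixture(scope="session")
def bladder():
    return load_fixture("bladder_cancer")


@pytest.fixture(scope="session")
def glass_ml(glass):
    return fit_ml(glass)


@pytest.fixture(scope="session")
def bladder_ml(bladder):
    return fit_ml(bladder)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240926)
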