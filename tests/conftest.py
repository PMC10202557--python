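import numpy as np
import pytest

from srcconn.headmodel import build_leadfield, make_solution_space
from srcconn.inverse import sloreta_operator
from srcconn.recording import MONTAGE_1020


@pytest.fixture(scope="session")
def space_test():
    return make_solution_space("test")


@pytest.fixture(scope="session")
def leadfield_test(space_test):
    return build_leadfield(MONTAGE_1020, space_test, model="three_shell_sphere")


@pytest.fixture(scope="session")
def operator_test(leadfield_test):
    return sloreta_operator(leadfield_test)


@pytest.fixture(scope="session")
def leadfield_synth(space_test):
    return build_leadfield(MONTAGE_1020, space_test, model="synthetic", seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
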