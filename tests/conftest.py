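import numpy as np
import pytest

from membranescatter.cd import default_basis
from membranescatter.peptides import fauchere_pliska_scale, parse_sequence
from membranescatter.sdp import SDPModel, SDPParams, default_composition

E2_35 = "RRVWRWVRRVWRWVRR"
E2_53R = "RRUXRXURRUXRXURR"
LE_54R = "RRRRRRRXXXXUUU"


@pytest.fixture(scope="session")
def fp_scale():
    return fauchere_pliska_scale()


@pytest.fixture(scope="session")
def e2_35():
    return parse_sequence(E2_35, name="E2-35")


@pytest.fixture(scope="session")
def basis():
    return default_basis(np.arange(200.0, 241.0, 1.0))


@pytest.fixture(scope="session")
def gneg():
    return default_composition("gneg_im")


@pytest.fixture(scope="session")
def control_model(gneg):
    return SDPModel(gneg, SDPParams(a_l=71.0))
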