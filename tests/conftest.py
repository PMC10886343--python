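import numpy as np
import pytest

from extractopt.datasets import load_compound_library, load_dateseed_design
from extractopt.rsm import QuadraticSurface


@pytest.fixture(scope="session")
def dateseed():
    """The 17-run study design plus TPC/TFC experimental responses."""
    design, responses = load_dateseed_design()
    return design, responses


@pytest.fixture(scope="session")
def tpc_model(dateseed):
    design, responses = dateseed
    return QuadraticSurface(response="TPC").fit(design.coded, responses["TPC"])


@pytest.fixture(scope="session")
def tfc_model(dateseed):
    design, responses = dateseed
    return QuadraticSurface(response="TFC").fit(design.coded, responses["TFC"])


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture
def rng():
    return np.random.default_rng(20240215)
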