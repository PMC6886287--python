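import numpy as np
import pytest

import autofmo as af


@pytest.fixture(scope="session")
def phantom():
    return af.generate_phantom(af.default_prostate_spec())


@pytest.fixture(scope="session")
def influence(phantom):
    return af.compute_influence_matrix(phantom, af.default_beam_spec())


@pytest.fixture(scope="session")
def prescription():
    return af.default_prostate_prescription()


@pytest.fixture(scope="session")
def dv_result(phantom, influence, prescription):
    """One shared end-to-end run of the automatic dose-volume loop."""
    return af.run_automatic(phantom, influence, prescription, model="dv")


@pytest.fixture(scope="session")
def geud_result(phantom, influence, prescription):
    return af.run_automatic(phantom, influence, prescription, model="geud")


@pytest.fixture(scope="session")
def ntcp_result(phantom, influence, prescription):
    return af.run_automatic(phantom, influence, prescription, model="ntcp")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
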