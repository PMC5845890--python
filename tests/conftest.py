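import logging

import pytest

from sensortrace import synthetic as G


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("sensortrace").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def atp_trace():
    return G.gen_atp_trace(seed=3)


@pytest.fixture(scope="session")
def redox_trace():
    return G.gen_redox_trace(fraction_reduced=0.95, seed=2)


@pytest.fixture(scope="session")
def dff_population():
    return G.gen_dff_population(n_neurons=100, responder_fraction=0.6, seed=5)


@pytest.fixture(scope="session")
def network_raster():
    return G.gen_network_raster(seed=7)
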