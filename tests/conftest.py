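import numpy as np
import pytest

from bidomainuq import build_mesh, mean_conductivities
from bidomainuq.pipeline import Simulator


@pytest.fixture(scope="session")
def tiny_mesh():
    return build_mesh("tiny")


@pytest.fixture(scope="session")
def mean_cset():
    return mean_conductivities()


@pytest.fixture(scope="session")
def tiny_simulator():
    """Session-wide cached finite-volume simulator on the tiny mesh."""
    return Simulator(backend="fv", mesh_preset="tiny")


@pytest.fixture(scope="session")
def mock_sim():
    return Simulator(backend="mock")


@pytest.fixture(scope="session")
def mean_epd_depth30(tiny_simulator):
    """One solved EPD at mean inputs, 30% depth (shared across tests)."""
    from bidomainuq.parameters import CONDUCTIVITY_NAMES, default_ranges

    r = default_ranges()
    params = {n: r.mean[r.index(n)] for n in ("ROT", "g_b") + CONDUCTIVITY_NAMES}
    return tiny_simulator(params, 0.3)
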