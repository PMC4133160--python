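import numpy as np
import pytest

from seizuresheet import build_geometry, load_preset
from seizuresheet.connectivity import ConnectivityParams
from seizuresheet.fixtures import make_test_fixture


@pytest.fixture(scope="session")
def standard_unit():
    return load_preset("standard")["unit"]


@pytest.fixture(scope="session")
def conn_params():
    return ConnectivityParams(**load_preset("standard").get("connectivity", {}))


@pytest.fixture(scope="session")
def torus_geom():
    return build_geometry(30, 30, macro_edge=10, pitch_um=50.0, boundary="torus")


@pytest.fixture(scope="session")
def zeroflux_geom():
    return build_geometry(30, 30, macro_edge=10, pitch_um=50.0, boundary="zero_flux")


@pytest.fixture(scope="session")
def small_sheet():
    """30x30 torus sheet with full three-type connectivity at preset
    parameters (session-scoped: connectivity sampling is the slow part)."""
    return make_test_fixture("small_sheet", seed=11)


@pytest.fixture(scope="session")
def small_sheet_zf():
    return make_test_fixture("small_sheet", seed=11, boundary="zero_flux")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
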