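import pytest

from sccosol.core_data import MeasurementGeometry, nhm_fixture


@pytest.fixture(scope="session")
def nhm():
    """Packaged 24-point dataset with its solute properties."""
    return nhm_fixture()


@pytest.fixture(scope="session")
def nhm_data(nhm):
    return nhm[0]


@pytest.fixture(scope="session")
def nhm_props(nhm):
    return nhm[1]


@pytest.fixture()
def geometry():
    return MeasurementGeometry(Vs=5e-3, Vl=600e-6)
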