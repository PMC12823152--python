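import numpy as np
import pytest

from sedgrid import BufferSpec, CellGeometry, buffer_state

RPM30K = 2.0 * np.pi * 30000 / 60.0


@pytest.fixture(scope="session")
def water_spec():
    """Plain water at 20 degC (no salt increment)."""
    return BufferSpec(base_density_increment=0.0)


@pytest.fixture(scope="session")
def water(water_spec):
    return buffer_state(water_spec)


@pytest.fixture(scope="session")
def pbs_spec():
    return BufferSpec()


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry()


@pytest.fixture(scope="session")
def omega():
    return RPM30K


@pytest.fixture(scope="session")
def scan_times():
    return np.linspace(600.0, 30000.0, 15)
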