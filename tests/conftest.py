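import numpy as np
import pytest

import heatwork as hw


@pytest.fixture(scope="session")
def calibration():
    return hw.load_calibration()


@pytest.fixture(scope="session")
def pooled(calibration):
    """Pooled calibration view: 22 (Ta, RH) conditions with mean PWC."""
    return calibration.pooled()


@pytest.fixture(scope="session")
def condition_grid():
    """Dense Ta x RH grid inside the calibration window, for property checks."""
    ta = np.arange(15.0, 50.5, 2.5)
    rh = np.arange(20.0, 80.5, 5.0)
    return np.meshgrid(ta, rh)


@pytest.fixture(scope="session")
def registry():
    return hw.default_registry()
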