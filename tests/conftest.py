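import numpy as np
import pytest

from endortools import AcquisitionParams, CSTensor, F19, SpinSystem


@pytest.fixture
def gd4_system():
    """No-CSA reference system: 19F at 13.3 A."""
    return SpinSystem(nucleus=F19, r_GdF=13.3)


@pytest.fixture
def gd1_system():
    """CSA reference system: 19F at 10.2 A."""
    return SpinSystem(nucleus=F19, r_GdF=10.2)


@pytest.fixture
def fluorobenzene_tensor():
    return CSTensor(dxx=98.0, dyy=-29.0, dzz=-69.0, gamma=57.0, rho=75.0)


@pytest.fixture
def acq():
    return AcquisitionParams(tau=2000e-9, nu_ref=136.4e6, lw_fwhm=15e3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
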