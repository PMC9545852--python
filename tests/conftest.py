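import numpy as np
import pytest

from vfat1.phantom import ScannerProfile, SubjectProfile
from vfat1.signal_models import Tissue, VfaAcquisition

LIVER_3T = 752.0
LIVER_15T = 602.0


@pytest.fixture
def liver_tissue():
    return Tissue(t1=LIVER_3T, m0=1000.0)


@pytest.fixture
def six_angle_acq():
    """Default six-flip-angle SPGR protocol at TR = 3.5 ms."""
    return VfaAcquisition(tr=3.5, flip_angles=(2.0, 5.0, 8.0, 10.0, 12.0, 15.0))


@pytest.fixture
def ideal_scanner():
    """Noiseless scanner with a uniform transmit field."""
    return ScannerProfile("X1", "S", 3.0, tr=3.5,
                          b1_field_params=(1.0, 0.0, 0.5), noise_sd=0.0,
                          has_molli=True)


@pytest.fixture
def subject():
    return SubjectProfile("sub01", liver_t1_15t=LIVER_15T, liver_t1_30t=LIVER_3T)


def spgr_forward(t1, tr, m0, angles_deg, k=1.0):
    """Closed-form SPGR evaluation independent of the package internals;
    used as the oracle for fit tests."""
    a = np.radians(k * np.asarray(angles_deg, dtype=float))
    e1 = np.exp(-tr / t1)
    return m0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
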