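import numpy as np
import pytest

from optisect.config import OpticalConfig, ScanConfig
from optisect.pupil import make_otf_grid


@pytest.fixture(scope="session")
def cfg():
    """Reference optical system: NA 1.0 water-immersion, green fluorescence."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def cfg_equal_wavelengths():
    """Excitation = emission wavelength, for checks against single-T theory."""
    return OpticalConfig(wavelength_ex=0.5, wavelength_em=0.5)


@pytest.fixture(scope="session")
def otf():
    """Default comparison OTF lattice (shared; ~6 s to build)."""
    return make_otf_grid()


@pytest.fixture(scope="session")
def fine_scan():
    """Noise-free scan geometry on a 0.1 um lattice for PSF-level checks."""
    return ScanConfig(pitch=0.3, scan_step=0.1, pixel_width=0.3, noise="none")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
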