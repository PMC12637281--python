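import numpy as np
import pytest

from spinpol import spinsim


@pytest.fixture(scope="session")
def sar1():
    """The dominant 13C-labeled stable alanine radical species."""
    return spinsim.carbon13_sar1()


@pytest.fixture(scope="session")
def isotropic_powder():
    return spinsim.OrientationDistribution(0.0)


@pytest.fixture(scope="session")
def grid_small():
    return spinsim.golden_spiral_grid(800)


@pytest.fixture(scope="session")
def grid_medium():
    return spinsim.golden_spiral_grid(3000)


@pytest.fixture(scope="session")
def narrow_gaussian_density():
    """A narrow symmetric g(omega): one Gaussian line at 188 GHz, 6.7 T."""
    axis = np.linspace(187.0, 189.0, 2001)
    sigma = 0.02
    dens = np.exp(-0.5 * ((axis - 188.0) / sigma) ** 2)
    dens /= np.trapezoid(dens, axis)
    return spinsim.SpectralDensity(axis, dens, 6.7, width_d_GHz=2 * sigma)
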