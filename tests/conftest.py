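import numpy as np
import pytest

from hemobc import fixtures as fx
from hemobc import waveform as wf

BLOOD_NU = 0.004 / 1060.0  # kinematic viscosity of blood, m^2/s


@pytest.fixture(scope="session")
def circle_patch():
    """Aortic-root-scale disk (R = 1 cm), default mesh density."""
    return fx.make_patch(fx.FixtureConfig(radius=0.01, n_rings=24))


@pytest.fixture(scope="session")
def fine_circle_patch():
    """Finer disk for quadrature-sensitive checks."""
    return fx.make_patch(fx.FixtureConfig(radius=0.01, n_rings=48))


@pytest.fixture(scope="session")
def unit_circle_patch():
    """Unit-radius disk used where closed forms are cleanest."""
    return fx.make_patch(fx.FixtureConfig(radius=1.0, n_rings=32))


@pytest.fixture(scope="session")
def aortic_waveform():
    return fx.make_waveform()


@pytest.fixture(scope="session")
def aortic_fourier(aortic_waveform):
    return wf.fit_fourier(aortic_waveform, 8)


@pytest.fixture(scope="session")
def constant_fourier():
    """Steady flow of 4e-4 m^3/s (24 L/min) at a 1 s period."""
    return wf.FourierWaveform(4.0e-4, np.zeros(0), np.zeros(0), 2.0 * np.pi)
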