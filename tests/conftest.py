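import numpy as np
import pytest

from dielmap import (
    DEFAULT_AXIS,
    ForwardModel,
    SpectralAxis,
    Spectrum,
    default_calibration,
)


@pytest.fixture(scope="session")
def axis() -> SpectralAxis:
    """The 32-channel 416-728 nm instrument axis."""
    return DEFAULT_AXIS


@pytest.fixture(scope="session")
def calibration():
    """A monotone synthetic calibration spanning [2, 80]."""
    return default_calibration()


@pytest.fixture(scope="session")
def forward_phase(calibration):
    """Forward model anchored so the phasor readout is self-consistent."""
    return ForwardModel(calibration=calibration, anchor="phase")


@pytest.fixture(scope="session")
def forward_mode(calibration):
    """Forward model anchored so the spectral mode matches the calibration."""
    return ForwardModel(calibration=calibration, anchor="mode")


def delta_spectrum(axis: SpectralAxis, channel: int, counts: float = 1.0) -> Spectrum:
    intens = np.zeros(axis.n_channels)
    intens[channel] = counts
    return Spectrum(axis, intens)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
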