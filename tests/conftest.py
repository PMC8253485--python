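import numpy as np
import pytest

from aquanmr import (
    BinnedSpectrum,
    CompoundEntry,
    LorentzianSignal,
    TargetSignal,
    synthesize_spectrum,
)


@pytest.fixture
def axis():
    """Small blank axis, 3.0-4.0 ppm at the standard 0.0002 ppm/bin, 600 MHz."""
    return BinnedSpectrum(3.0, 0.0002, np.zeros(5001), 600.0, id="axis")


@pytest.fixture
def ramp_spectrum():
    return BinnedSpectrum(3.0, 0.0002, np.linspace(0.0, 5.0, 2001), 600.0, id="ramp")


def lorentzian_spectrum(signals, axis):
    """Closed-form Lorentzian mixture on an axis (thin wrapper for tests)."""
    return synthesize_spectrum([LorentzianSignal(*s) for s in signals], axis)


@pytest.fixture
def separated_pair(axis):
    """Two singlet compounds far apart: their interference matrix is I."""
    lib = [
        CompoundEntry(
            "cpd_a", reporter_ppm=3.2, response_factor=10.0,
            signals=[LorentzianSignal(3.2, 1.5, 1.0)],
        ),
        CompoundEntry(
            "cpd_b", reporter_ppm=3.9, response_factor=20.0,
            signals=[LorentzianSignal(3.9, 1.5, 1.0)],
        ),
    ]
    targets = [
        TargetSignal("cpd_a", 3.2, 0.0002),
        TargetSignal("cpd_b", 3.9, 0.0002),
    ]
    return lib, targets


@pytest.fixture
def triangular_pair(axis):
    """Binned calibrations crafted so m = [[1, 0.5], [0, 1]] exactly:
    compound B contributes height 0.5 at A's target, nothing conversely."""
    bin_a = 1000  # 3.2 ppm
    bin_b = 4500  # 3.9 ppm
    cal_a = np.zeros(axis.n_bins)
    cal_a[bin_a] = 2.0  # un-normalized; reporter scale 2
    cal_b = np.zeros(axis.n_bins)
    cal_b[bin_b] = 4.0
    cal_b[bin_a] = 2.0  # 0.5 after normalization
    mk = lambda v, i: BinnedSpectrum(3.0, 0.0002, v, 600.0, id=i)
    lib = [
        CompoundEntry("cpd_a", reporter_ppm=3.2, response_factor=10.0,
                      spectrum=mk(cal_a, "cal_a")),
        CompoundEntry("cpd_b", reporter_ppm=3.9, response_factor=20.0,
                      spectrum=mk(cal_b, "cal_b")),
    ]
    targets = [
        TargetSignal("cpd_a", 3.2, 0.0002),
        TargetSignal("cpd_b", 3.9, 0.0002),
    ]
    return lib, targets
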