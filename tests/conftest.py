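import numpy as np
import pytest

from flimbench.core import TimeAxis, bench_axis, camera_axis
from flimbench.synthetic import simulate_irf


@pytest.fixture(scope="session")
def bench():
    return bench_axis()


@pytest.fixture(scope="session")
def camera():
    return camera_axis()


@pytest.fixture(scope="session")
def bench_irf(bench):
    """Gaussian bench IRF: 250 ps FWHM centered at 2 ns."""
    return simulate_irf(bench, fwhm=0.25, center=2.0)


@pytest.fixture(scope="session")
def camera_irf(camera):
    """One-bin-wide camera IRF: 370 ps FWHM centered at 1 ns."""
    return simulate_irf(camera, fwhm=0.37, center=1.0)


@pytest.fixture
def small_axis():
    """Coarse 64-bin grid over 12.5 ns for brute-force oracles."""
    return TimeAxis(bin_width=12.5 / 64, n_bins=64, period=12.5)


def circular_convolve_oracle(kernel: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Independent periodic-convolution reference: aperiodic convolution folded
    back over the period (the definition of circular convolution, computed
    without FFTs)."""
    full = np.convolve(kernel, weights)
    out = np.zeros(kernel.size)
    for start in range(0, full.size, kernel.size):
        chunk = full[start : start + kernel.size]
        out[: chunk.size] += chunk
    return out
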