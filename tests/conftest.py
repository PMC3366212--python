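import numpy as np
import pytest

from dialyspec import SimConfig, Spectrum, WAVELENGTH_GRID, simulate_dataset


@pytest.fixture(scope="session")
def grid():
    return WAVELENGTH_GRID


@pytest.fixture
def zero_absorbance(grid):
    return Spectrum(grid, np.zeros(grid.size), "absorbance")


@pytest.fixture
def zero_derivative(grid):
    return Spectrum(grid, np.zeros(grid.size), "derivative")


@pytest.fixture(scope="session")
def small_dataset():
    """20-session noisy dataset shared by read-only tests."""
    config = SimConfig(n_sessions=20, cal_count=12, seed=7)
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def noiseless_dataset():
    config = SimConfig(
        n_sessions=16, cal_count=10, noise_sd_au=0.0, baseline_drift_sd=0.0,
        seed=11,
    )
    return simulate_dataset(config)
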