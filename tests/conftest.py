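import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from specphot.spectra import (
    EmissionSpectrum,
    ReferenceSet,
    WavelengthGrid,
    builtin_reference_set,
    peak_normalize,
)
from specphot.synthetic import simulate_session

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# scaled-down acquisition used throughout the unit tests (5x fewer frames,
# 2-nm grid, 1-min gaps) -- same effects, kinetics and noise model
FAST = dict(frame_rate=5.0, grid_step_nm=2.0, inter_epoch_gap_s=60.0)


@pytest.fixture(scope="session")
def refset():
    return builtin_reference_set()


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid(np.arange(480.0, 651.0, 1.0))


@pytest.fixture
def two_disjoint(grid):
    """Two reference spectra with disjoint support (orthogonal columns)."""
    wl = grid.wavelengths
    a = np.where(wl < 550, np.exp(-0.5 * ((wl - 510) / 10) ** 2), 0.0)
    b = np.where(wl >= 550, np.exp(-0.5 * ((wl - 600) / 10) ** 2), 0.0)
    return ReferenceSet.from_spectra(
        [
            peak_normalize(EmissionSpectrum("a", grid, a)),
            peak_normalize(EmissionSpectrum("b", grid, b)),
        ]
    )


@pytest.fixture(scope="session")
def fast_session():
    """One scaled-down noisy fig1h session."""
    return simulate_session("fig1h", seed=7, **FAST)


@pytest.fixture(scope="session")
def noiseless_session():
    return simulate_session("fig1h", seed=0, noise_scale=0.0, **FAST)
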