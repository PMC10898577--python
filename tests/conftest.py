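import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dtofsense import (
    Inclusion,
    NoiseConfig,
    OpticalProperties,
    OptodeGeometry,
    SweepGrid,
    TimeGrid,
    simulate_sweep,
)
from dtofsense.dtof import moments_from_counts, truncation_window
from dtofsense.metrics import photon_noise_sd
from dtofsense.pipeline import assemble_maps

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def props10() -> OpticalProperties:
    """Study optics: µa = 0.1 cm⁻¹, µs′ = 10 cm⁻¹, water-based phantom."""
    return OpticalProperties(0.1, 10.0)


@pytest.fixture(scope="session")
def geometry() -> OptodeGeometry:
    return OptodeGeometry()


@pytest.fixture(scope="session")
def tg1024() -> TimeGrid:
    return TimeGrid(10_000.0, 1024)


@pytest.fixture(scope="session")
def reduced_grid() -> SweepGrid:
    """Down-sampled sweep raster keeping the full depth range."""
    return SweepGrid.from_extents(60, 4, 34, 2, 12, 3, 2)


@pytest.fixture(scope="session")
def reduced_sweep(props10, geometry, reduced_grid, tg1024):
    """Noiseless Born sweep at the study conditions on the reduced raster."""
    return simulate_sweep(
        props10, geometry, reduced_grid, Inclusion(), NoiseConfig(poisson=False),
        seed=0, time_grid=tg1024, n_replicates=1,
    )


@pytest.fixture(scope="session")
def reduced_maps(reduced_sweep):
    return assemble_maps(reduced_sweep)


@pytest.fixture(scope="session")
def reduced_noise(reduced_sweep, tg1024):
    """Theoretical photon-noise model from the baseline far/near moments."""
    t = tg1024.centers
    moms = {}
    for ch in ("left_2", "left_1"):
        counts = reduced_sweep.baselines[ch].mean(axis=0)
        lo, hi = truncation_window(counts)
        moms[ch] = moments_from_counts(t[lo:hi], counts[lo:hi])
    return photon_noise_sd(moms["left_2"], moms["left_1"])
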