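"""Synthetic liquid-phantom sweep experiment.

Generates the full in-silico counterpart of a tank experiment in which a
small absorbing cylinder is stepped through a cuboid volume of a
homogeneous scattering liquid while four source-detector channels record
DTOFs: two sources flanking two closely spaced detectors, far separation
3 cm and near separation 2.5 cm.

For every channel and absorber position the perturbed curve is the
baseline diffuse-reflectance curve plus the Born absorption sensitivity
kernel times the inclusion strength (-Δµa·ΔV), floored at zero.  Curves
are then broadened by the instrument response function (IRF), scaled to
the expected photon budget, optionally distorted by dead-time counting
loss driven by the companion channel sharing the detector, and sampled
with Poisson counting noise per replicate.

The "black" physical absorber of a real experiment is far beyond the
linear (Born) regime; the simulator instead uses a configurable effective
strength whose default produces a peak attenuation change |ΔA| ≈ 0.1,
comfortably inside linearity.  Matching the magnitudes of a physical
absorber is explicitly not attempted; the simulator exists so that every
analysis stage can be exercised end to end, with known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .forward import (
    OpticalProperties,
    OptodeGeometry,
    TimeGrid,
    absorption_jacobian_td,
    reflectance_td,
)

__all__ = [
    "SweepGrid",
    "Inclusion",
    "NoiseConfig",
    "DeadTimeModel",
    "SweepDataset",
    "gaussian_irf",
    "apply_irf",
    "add_poisson_noise",
    "apply_deadtime",
    "correct_deadtime",
    "simulate_sweep",
]


@dataclass(frozen=True)
class SweepGrid:
    """Absorber positions on a cuboid raster (mm).

    Coordinates are right-handed with the boundary plane at Z = 0, Z depth
    into the medium, X along the optode line centered on the detector
    midpoint, and Y transverse.  Positions refer to the inclusion centroid
    and must lie strictly inside the medium.

    The sweep enumeration order is Y fastest, then Z, then X, so that the
    flat position index reshapes to a (nx, nz, ny) map in C order.
    """

    x_mm: np.ndarray
    z_mm: np.ndarray
    y_mm: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x_mm", "z_mm", "y_mm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            object.__setattr__(self, name, arr)
        if np.any(self.z_mm <= 0):
            raise ValueError("absorber centers must lie strictly inside the medium (Z > 0)")

    @classmethod
    def from_extents(
        cls,
        x_extent_mm: float = 75.0,
        x_step_mm: float = 2.0,
        z_extent_mm: float = 35.0,
        z_step_mm: float = 2.0,
        y_extent_mm: float = 20.0,
        y_step_mm: float = 1.0,
        z_start_mm: float = 2.0,
    ) -> "SweepGrid":
        """Raster matching the study sweep: 75 × 35 × 20 mm cuboid, steps
        2 mm in X and Z and 1 mm in Y, X and Y centered on the detector
        midpoint, first Z plane at ``z_start_mm``."""

        def axis(extent: float, step: float) -> np.ndarray:
            n = int(np.floor(extent / step)) + 1
            span = (n - 1) * step
            return -span / 2.0 + step * np.arange(n)

        nx = int(np.floor(x_extent_mm / x_step_mm)) + 1
        nz = int(np.floor(z_extent_mm / z_step_mm)) + 1
        ny = int(np.floor(y_extent_mm / y_step_mm)) + 1
        x = -((nx - 1) * x_step_mm) / 2.0 + x_step_mm * np.arange(nx)
        z = z_start_mm + z_step_mm * np.arange(nz)
        y = -((ny - 1) * y_step_mm) / 2.0 + y_step_mm * np.arange(ny)
        return cls(x_mm=x, z_mm=z, y_mm=y)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x_mm.size, self.z_mm.size, self.y_mm.size)

    @property
    def n_positions(self) -> int:
        nx, nz, ny = self.shape
        return nx * nz * ny

    def positions_mm(self) -> np.ndarray:
        """(n, 3) array of (x, y, z) in mm, in sweep order."""
        X, Z, Y = np.meshgrid(self.x_mm, self.z_mm, self.y_mm, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def positions_cm(self) -> np.ndarray:
        return self.positions_mm() / 10.0


@dataclass(frozen=True)
class Inclusion:
    """Small absorbing cylinder stepped through the phantom.

    The Born-level perturbation strength is the product Δµa · volume
    (cm⁻¹·cm³).  The default Δµa = 0.1 cm⁻¹ over the 3 mm × 5 mm cylinder
    yields a peak attenuation change of ≈0.1 on the far channel at the
    default optics, inside the linear regime.
    """

    diameter_mm: float = 3.0
    height_mm: float = 5.0
    delta_mu_a: float = 0.1  # cm^-1

    @property
    def volume_cm3(self) -> float:
        r = self.diameter_mm / 20.0  # cm
        return float(np.pi * r**2 * self.height_mm / 10.0)

    @property
    def strength(self) -> float:
        """Δµa · volume, the Born perturbation magnitude (cm⁻¹·cm³)."""
        return self.delta_mu_a * self.volume_cm3


@dataclass(frozen=True)
class DeadTimeModel:
    """Non-paralyzable counting-loss cross-talk between companion channels.

    With interleaved lasers, the two DTOFs recorded by one detector share
    its counting electronics; the dead time triggered by photons of one
    laser removes counting capacity from the other.  Modeled as a uniform
    non-paralyzable scaling: the measured counts of channel A are

        m_A = n_A / (1 + r_B τ),   r_B = n_B / T,

    with τ the dead time per event and T the acquisition time.  The
    correction inverts the coupled pair exactly.
    """

    tau_ns: float = 100.0
    acquisition_time_s: float = 0.09

    @property
    def _u(self) -> float:
        """τ/T in units of 1/counts."""
        return self.tau_ns * 1e-9 / self.acquisition_time_s

    def apply(self, n_a: float, n_b: float) -> tuple[float, float]:
        u = self._u
        return n_a / (1.0 + u * n_b), n_b / (1.0 + u * n_a)

    def correct(self, m_a: float, m_b: float) -> tuple[float, float]:
        u = self._u
        denom = 1.0 - m_a * m_b * u**2
        if denom <= 0:
            raise ValueError("measured rates imply a non-physical true rate")
        n_a = m_a * (1.0 + u * m_b) / denom
        n_b = m_b * (1.0 + u * m_a) / denom
        return n_a, n_b


def apply_deadtime(counts_a: np.ndarray, counts_b: np.ndarray, model: DeadTimeModel):
    """Scale a companion pair of histograms by their mutual counting loss."""
    n_a, n_b = float(np.sum(counts_a)), float(np.sum(counts_b))
    m_a, m_b = model.apply(n_a, n_b)
    fa = m_a / n_a if n_a > 0 else 1.0
    fb = m_b / n_b if n_b > 0 else 1.0
    return np.asarray(counts_a) * fa, np.asarray(counts_b) * fb


def correct_deadtime(counts_a: np.ndarray, counts_b: np.ndarray, model: DeadTimeModel):
    """Invert :func:`apply_deadtime` on a companion pair of histograms."""
    m_a, m_b = float(np.sum(counts_a)), float(np.sum(counts_b))
    n_a, n_b = model.correct(m_a, m_b)
    fa = n_a / m_a if m_a > 0 else 1.0
    fb = n_b / m_b if m_b > 0 else 1.0
    return np.asarray(counts_a) * fa, np.asarray(counts_b) * fb


@dataclass(frozen=True)
class NoiseConfig:
    """Photon budget, IRF, and counting-noise settings.

    ``count_rate_per_detector`` is the summed rate of the two DTOFs a
    detector records per second; each replicate integrates for
    ``collection_time_s``.  The per-channel expected counts split the
    detector budget proportionally to the model curve integrals.
    """

    count_rate_per_detector: float = 3.5e6  # counts/s, sum of two DTOFs
    collection_time_s: float = 0.09
    irf_fwhm_ps: float = 650.0
    irf_t0_ps: float = 1000.0
    poisson: bool = True
    deadtime: Optional[DeadTimeModel] = None


@dataclass
class SweepDataset:
    """All DTOF stacks of one synthetic sweep.

    ``channels[name]`` has shape (n_positions, n_replicates, n_bins);
    ``baselines[name]`` has shape (n_replicates, n_bins) and holds
    absorber-absent recordings.  Counts are real-valued (Poisson draws are
    integers, expected curves are not).
    """

    time_grid: TimeGrid
    grid: SweepGrid
    geometry: OptodeGeometry
    props: OpticalProperties
    channels: dict[str, np.ndarray]
    baselines: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    @property
    def channel_names(self) -> list[str]:
        return sorted(self.channels)

    @property
    def n_replicates(self) -> int:
        return next(iter(self.channels.values())).shape[1]


def gaussian_irf(grid: TimeGrid, fwhm_ps: float, t0_ps: float) -> np.ndarray:
    """Unit-integral Gaussian IRF sampled at the grid bin centers."""
    sigma = fwhm_ps / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = grid.centers
    irf = np.exp(-0.5 * ((t - t0_ps) / sigma) ** 2)
    return irf / (irf.sum() * grid.dt)


def apply_irf(curve: np.ndarray, irf: np.ndarray, dt: float) -> np.ndarray:
    """Discrete linear convolution with the IRF, truncated to the grid.

    Works on a single curve or a batch of rows.  The integral is preserved
    up to the truncated tail mass when the IRF has unit integral
    (Σ irf · dt = 1).
    """
    curve = np.asarray(curve, dtype=float)
    irf = np.asarray(irf, dtype=float)
    n = irf.size
    nfft = 2 * n
    batch = np.atleast_2d(curve)
    out = np.fft.irfft(np.fft.rfft(batch, nfft) * np.fft.rfft(irf, nfft), nfft)[:, :n] * dt
    out = np.clip(out, 0.0, None)
    return out[0] if curve.ndim == 1 else out


def add_poisson_noise(curve: np.ndarray, total_counts: float, rng) -> np.ndarray:
    """Poisson counts with expectation ``curve`` scaled to ``total_counts``.

    ``rng`` is a seeded :class:`numpy.random.Generator` (or an int seed).
    Zero bins stay zero.
    """
    if np.isscalar(rng) or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    curve = np.asarray(curve, dtype=float)
    if np.any(curve < 0):
        raise ValueError("expected curve must be non-negative")
    s = curve.sum()
    if s <= 0 or total_counts <= 0:
        raise ValueError("need positive curve mass and total_counts")
    return rng.poisson(curve * (total_counts / s)).astype(float)


def _expected_channel_counts(
    props: OpticalProperties, geometry: OptodeGeometry, noise: NoiseConfig
) -> dict[str, float]:
    """Split each detector's photon budget between its two source channels
    proportionally to the model curve integrals."""
    from .forward import theoretical_moments

    integral = {
        ch: theoretical_moments(props, geometry.separation(ch)).N
        for ch in geometry.channels
    }
    budget = noise.count_rate_per_detector * noise.collection_time_s
    counts: dict[str, float] = {}
    for det in ("1", "2"):
        members = [ch for ch, (_, d) in geometry.channels.items() if d == det]
        tot = sum(integral[ch] for ch in members)
        for ch in members:
            counts[ch] = budget * integral[ch] / tot
    return counts


def simulate_sweep(
    props: OpticalProperties,
    geometry: OptodeGeometry,
    grid: SweepGrid,
    inclusion: Inclusion,
    noise: NoiseConfig,
    seed: int,
    time_grid: Optional[TimeGrid] = None,
    n_replicates: int = 20,
    boundary: str = "extrapolated",
) -> SweepDataset:
    """Generate the four-channel DTOF stack for every absorber position.

    Deterministic given (configuration, seed).  With ``noise.poisson``
    False the replicates repeat the expected (noise-free) counts and
    ``n_replicates`` is typically set to 1.
    """
    if time_grid is None:
        time_grid = TimeGrid()
    rng = np.random.default_rng(seed)
    positions = grid.positions_cm()
    dt = time_grid.dt
    irf = gaussian_irf(time_grid, noise.irf_fwhm_ps, noise.irf_t0_ps)
    target_counts = _expected_channel_counts(props, geometry, noise)

    # expected (noise-free) per-bin count curves, before dead time
    expected: dict[str, np.ndarray] = {}
    base_expected: dict[str, np.ndarray] = {}
    born_warnings: list[str] = []
    for ch, (src_name, det_name) in geometry.channels.items():
        src = geometry.source_positions[src_name]
        det = geometry.detector_positions[det_name]
        rho = geometry.separation(ch)
        base = reflectance_td(props, rho, time_grid, boundary)
        K = absorption_jacobian_td(props, src, det, positions, time_grid, boundary)
        pert = base[None, :] - inclusion.strength * K
        removed = 1.0 - pert.sum(axis=1) / base.sum()
        if np.any(removed > 0.5):
            born_warnings.append(
                f"channel {ch}: perturbation removes >50% of curve mass at "
                f"{int(np.sum(removed > 0.5))} positions; Born linearity is violated"
            )
        pert = np.clip(pert, 0.0, None)
        base_c = apply_irf(base, irf, dt)
        pert_c = apply_irf(pert, irf, dt)
        scale = target_counts[ch] / (base_c.sum() * dt)
        base_expected[ch] = base_c * dt * scale
        expected[ch] = pert_c * dt * scale
    for msg in born_warnings:
        warnings.warn(msg)

    if noise.deadtime is not None:
        for det in ("1", "2"):
            a, b = (ch for ch, (_, d) in geometry.channels.items() if d == det)
            expected[a], expected[b] = _apply_deadtime_rows(
                expected[a], expected[b], noise.deadtime
            )
            base_expected[a], base_expected[b] = apply_deadtime(
                base_expected[a], base_expected[b], noise.deadtime
            )

    channels: dict[str, np.ndarray] = {}
    baselines: dict[str, np.ndarray] = {}
    n_bins = time_grid.n_bins
    for ch in sorted(geometry.channels):
        exp = expected[ch]
        if noise.poisson:
            stack = rng.poisson(exp[:, None, :].repeat(n_replicates, axis=1)).astype(float)
            base_stack = rng.poisson(
                base_expected[ch][None, :].repeat(n_replicates, axis=0)
            ).astype(float)
        else:
            stack = np.broadcast_to(exp[:, None, :], (exp.shape[0], n_replicates, n_bins)).copy()
            base_stack = np.broadcast_to(
                base_expected[ch], (n_replicates, n_bins)
            ).copy()
        channels[ch] = stack
        baselines[ch] = base_stack

    metadata = {
        "seed": int(seed),
        "n_replicates": int(n_replicates),
        "inclusion": {
            "diameter_mm": inclusion.diameter_mm,
            "height_mm": inclusion.height_mm,
            "delta_mu_a": inclusion.delta_mu_a,
        },
        "noise": {
            "count_rate_per_detector": noise.count_rate_per_detector,
            "collection_time_s": noise.collection_time_s,
            "irf_fwhm_ps": noise.irf_fwhm_ps,
            "irf_t0_ps": noise.irf_t0_ps,
            "poisson": noise.poisson,
            "deadtime_tau_ns": noise.deadtime.tau_ns if noise.deadtime else None,
        },
        "boundary": boundary,
        "born_warnings": born_warnings,
    }
    return SweepDataset(
        time_grid=time_grid,
        grid=grid,
        geometry=geometry,
        props=props,
        channels=channels,
        baselines=baselines,
        metadata=metadata,
    )


def _apply_deadtime_rows(rows_a: np.ndarray, rows_b: np.ndarray, model: DeadTimeModel):
    """Row-wise dead-time application for matching position stacks."""
    out_a = np.empty_like(rows_a)
    out_b = np.empty_like(rows_b)
    for i in range(rows_a.shape[0]):
        out_a[i], out_b[i] = apply_deadtime(rows_a[i], rows_b[i], model)
    return out_a, out_b
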