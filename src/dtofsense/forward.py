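"""Time-resolved diffusion forward model for a semi-infinite turbid medium.

The medium fills the half-space z > 0 (units: cm, ps).  Light transport is
described by the diffusion approximation with diffusion coefficient
D = 1/(3 µs′) (absorption-independent convention) and energy speed
v = c / n.  The boundary is handled with the extrapolated-boundary method:
the fluence vanishes on the plane z = -z_b, with z_b = 2 A D and A the
internal-reflection parameter of the Groenhuis/Egan approximation.  The
Green's function is then the free-space diffusion kernel minus its mirror
image about the extrapolated plane (a negative image source).

The detected time-resolved signal for a source-detector pair is modeled as
this boundary Green's function evaluated between an effective source point
and an effective detector point, each buried one transport mean free path
z0 = 1/µs′ below the surface.  This choice makes three things mutually
exact, which the rest of the package relies on:

* absorption enters every curve only through the factor exp(-µa v t);
* the Green's function obeys the Chapman-Kolmogorov semigroup property, so
  the Born absorption Jacobian is the time convolution of the
  source-to-voxel and voxel-to-detector kernels; and
* the voxel-volume integral of the Jacobian at fixed t equals v·t·R(t)
  (the mean total photon pathlength at arrival time t is exactly v·t).

Statistical moments of the model curve have closed forms in terms of
modified Bessel functions K_ν, used both directly and as the inner loop of
moment-based optical-property estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .dtof import MomentSet

__all__ = [
    "C_VACUUM_CM_PS",
    "OpticalProperties",
    "OptodeGeometry",
    "TimeGrid",
    "internal_reflection_parameter",
    "reflectance_td",
    "greens_fluence",
    "absorption_jacobian_td",
    "theoretical_moments",
    "estimate_optical_properties",
]

C_VACUUM_CM_PS = 0.0299792458  # speed of light in vacuum, cm/ps


def internal_reflection_parameter(n: float) -> float:
    """Internal-reflection parameter A(n) (Groenhuis/Egan approximation).

    A = (1 + r_d) / (1 - r_d) with r_d ≈ -1.440 n⁻² + 0.710 n⁻¹ + 0.668 +
    0.0636 n, for a medium of refractive index n against air.
    """
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the homogeneous medium.

    mu_a and mu_s_prime in cm⁻¹; n dimensionless (>= 1).
    """

    mu_a: float
    mu_s_prime: float
    n: float = 1.33

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ValueError("mu_a and mu_s_prime must be positive")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def v(self) -> float:
        """Energy speed of light in the medium, cm/ps."""
        return C_VACUUM_CM_PS / self.n

    @property
    def D(self) -> float:
        """Diffusion coefficient 1/(3 µs′), cm."""
        return 1.0 / (3.0 * self.mu_s_prime)

    @property
    def z0(self) -> float:
        """Effective isotropic-source depth, one transport mean free path (cm)."""
        return 1.0 / self.mu_s_prime

    def zb(self, boundary: str = "extrapolated") -> float:
        """Extrapolation length z_b = 2 A D (cm); 0 for the zero-boundary model."""
        if boundary == "zero":
            return 0.0
        if boundary != "extrapolated":
            raise ValueError(f"unknown boundary model {boundary!r}")
        return 2.0 * internal_reflection_parameter(self.n) * self.D


@dataclass(frozen=True)
class OptodeGeometry:
    """Two sources flanking two detectors on the surface z = 0, all on the x axis.

    The far pairs (left source-detector 2, right source-detector 1) share
    ``far_separation``; the near pairs (left-1, right-2) share
    ``near_separation``.  The layout is symmetric about the detector
    midpoint, which is the coordinate origin.
    """

    far_separation: float = 3.0  # cm
    near_separation: float = 2.5  # cm

    def __post_init__(self) -> None:
        if not 0 < self.near_separation < self.far_separation:
            raise ValueError("need 0 < near_separation < far_separation")

    @property
    def detector_half_spacing(self) -> float:
        return (self.far_separation - self.near_separation) / 2.0

    @property
    def source_half_spacing(self) -> float:
        return (self.far_separation + self.near_separation) / 2.0

    @property
    def source_positions(self) -> dict[str, np.ndarray]:
        xs = self.source_half_spacing
        return {"left": np.array([-xs, 0.0, 0.0]), "right": np.array([xs, 0.0, 0.0])}

    @property
    def detector_positions(self) -> dict[str, np.ndarray]:
        xd = self.detector_half_spacing
        return {"1": np.array([-xd, 0.0, 0.0]), "2": np.array([xd, 0.0, 0.0])}

    @property
    def channels(self) -> dict[str, tuple[str, str]]:
        """Channel name -> (source, detector), all four pairs."""
        return {
            "left_1": ("left", "1"),
            "left_2": ("left", "2"),
            "right_1": ("right", "1"),
            "right_2": ("right", "2"),
        }

    def separation(self, channel: str) -> float:
        src, det = self.channels[channel]
        s = self.source_positions[src]
        d = self.detector_positions[det]
        return float(np.linalg.norm(s - d))

    @property
    def far_channels(self) -> tuple[str, str]:
        return ("left_2", "right_1")

    @property
    def near_channels(self) -> tuple[str, str]:
        return ("left_1", "right_2")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid; bin centers at (k + 1/2)·dt to avoid t = 0."""

    t_stop: float = 10_000.0  # ps
    n_bins: int = 4096
    t_start: float = 0.0

    @property
    def dt(self) -> float:
        return (self.t_stop - self.t_start) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return self.t_start + (np.arange(self.n_bins) + 0.5) * self.dt


def _free_kernel(r: np.ndarray, t: np.ndarray, props: OpticalProperties) -> np.ndarray:
    """Free-space diffusion kernel, normalized so its volume integral is exp(-µa v t).

    r may be scalar or (n_points,); t is (n_bins,).  Returns broadcasted
    ( ..., n_bins).
    """
    Dv = props.D * props.v
    r = np.atleast_1d(np.asarray(r, dtype=float))[..., None]
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        out = (4.0 * np.pi * Dv * t) ** -1.5 * np.exp(
            -(r**2) / (4.0 * Dv * t) - props.mu_a * props.v * t
        )
    return out


def _mirror(p: np.ndarray, zb: float) -> np.ndarray:
    """Mirror point(s) about the extrapolated plane z = -zb."""
    q = np.array(p, dtype=float, copy=True)
    q[..., 2] = -2.0 * zb - q[..., 2]
    return q


def greens_fluence(
    props: OpticalProperties,
    r_a: np.ndarray,
    r_b: np.ndarray,
    grid: TimeGrid,
    boundary: str = "extrapolated",
) -> np.ndarray:
    """Boundary Green's function between two points of the half-space.

    ``r_a`` is a single 3-D point (cm); ``r_b`` a point or an (n, 3) array.
    Returns the kernel evaluated at the grid bin centers, shape (n_bins,) or
    (n, n_bins).  Symmetric in r_a <-> r_b and zero on the extrapolated
    plane z = -z_b.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b_in = np.asarray(r_b, dtype=float)
    single = r_b_in.ndim == 1
    r_b_in = np.atleast_2d(r_b_in)
    zb = props.zb(boundary)
    d_real = np.linalg.norm(r_b_in - r_a, axis=-1)
    if np.any(d_real == 0.0):
        raise ValueError("greens_fluence is singular for coincident points")
    d_image = np.linalg.norm(_mirror(r_b_in, zb) - r_a, axis=-1)
    t = grid.centers
    out = _free_kernel(d_real, t, props) - _free_kernel(d_image, t, props)
    return out[0] if single else out


def _effective_endpoints(
    props: OpticalProperties, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    z0 = props.z0
    return np.array([0.0, 0.0, z0]), np.array([rho, 0.0, z0])


def reflectance_td(
    props: OpticalProperties,
    rho: float,
    grid: TimeGrid,
    boundary: str = "extrapolated",
    check_coverage: bool = True,
) -> np.ndarray:
    """Time-resolved detected signal for one source-detector separation.

    Boundary Green's function between effective source and detector points
    buried at z0 = 1/µs′, at separation ``rho`` (cm).  Unnormalized photon
    density per bin; multiply by bin width and a count scale to obtain
    expected counts.

    Raises if the grid fails to contain the curve (last-bin value above
    1e-6 of the peak), naming the uncovered fraction.
    """
    if rho <= 0:
        raise ValueError("separation rho must be positive")
    r_s, r_d = _effective_endpoints(props, rho)
    curve = greens_fluence(props, r_s, r_d, grid, boundary)
    if check_coverage and curve[-1] > 1e-6 * curve.max():
        frac = curve[-1] / curve.max()
        raise ValueError(
            f"time grid too short: final bin holds {frac:.2e} of the peak value; "
            "extend t_stop"
        )
    return curve


def absorption_jacobian_td(
    props: OpticalProperties,
    source: np.ndarray,
    detector: np.ndarray,
    voxels: np.ndarray,
    grid: TimeGrid,
    boundary: str = "extrapolated",
) -> np.ndarray:
    """Born sensitivity kernel of the detected signal to a local µa change.

    For voxel centers ``voxels`` (shape (n, 3) or (3,), cm, z > 0) returns
    K(t) with shape (n, n_bins) (or (n_bins,)) such that a small absorption
    increase Δµa over a voxel volume ΔV changes the detected curve by

        ΔR(t) = -Δµa · ΔV · K(t),

    where K = v · (G_source→voxel ⊛_t G_voxel→detector), the time
    convolution evaluated as a discrete sum on the grid.  Source and
    detector are surface optode positions; they are buried to their
    effective depth z0 internally.
    """
    voxels_in = np.asarray(voxels, dtype=float)
    single = voxels_in.ndim == 1
    voxels = np.atleast_2d(voxels_in)
    if np.any(voxels[:, 2] <= 0):
        raise ValueError("voxel centers must lie strictly inside the medium (z > 0)")
    z0 = props.z0
    src = np.array(source, dtype=float)
    det = np.array(detector, dtype=float)
    if src[2] == 0.0:
        src = src + [0.0, 0.0, z0]
    if det[2] == 0.0:
        det = det + [0.0, 0.0, z0]
    n = grid.n_bins
    nfft = 2 * n
    K = np.empty((voxels.shape[0], n))
    # chunked so large voxel grids stay within memory
    chunk = max(1, int(2e7 / nfft))
    for i in range(0, voxels.shape[0], chunk):
        sl = slice(i, i + chunk)
        g_s = np.atleast_2d(greens_fluence(props, src, voxels[sl], grid, boundary))
        g_d = np.atleast_2d(greens_fluence(props, det, voxels[sl], grid, boundary))
        conv = np.fft.irfft(np.fft.rfft(g_s, nfft) * np.fft.rfft(g_d, nfft), nfft)[:, :n]
        K[sl] = props.v * conv * grid.dt
    return K[0] if single else K


def absorption_jacobian_at_time(
    props: OpticalProperties,
    source: np.ndarray,
    detector: np.ndarray,
    voxels: np.ndarray,
    t: float,
    n_quad: int = 512,
    boundary: str = "extrapolated",
) -> np.ndarray:
    """Born sensitivity kernel K at a single arrival time t (ps).

    Midpoint-rule evaluation of v·∫0^t G_s(t') G_d(t - t') dt' for many
    voxels at once; cheap enough for dense voxel grids where the full
    time-resolved kernel would not fit in memory.  Useful for pathlength
    checks: Σ_vox K(t)·ΔV = v · t · R(t).
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    if np.any(voxels[:, 2] <= 0):
        raise ValueError("voxel centers must lie strictly inside the medium (z > 0)")
    z0 = props.z0
    src = np.array(source, dtype=float)
    det = np.array(detector, dtype=float)
    if src[2] == 0.0:
        src = src + [0.0, 0.0, z0]
    if det[2] == 0.0:
        det = det + [0.0, 0.0, z0]
    dt = t / n_quad
    tq = (np.arange(n_quad) + 0.5) * dt
    zb = props.zb(boundary)
    out = np.empty(voxels.shape[0])
    chunk = max(1, int(2e7 / n_quad))
    for i in range(0, voxels.shape[0], chunk):
        sl = slice(i, i + chunk)
        d_s = np.linalg.norm(voxels[sl] - src, axis=-1)
        d_si = np.linalg.norm(_mirror(voxels[sl], zb) - src, axis=-1)
        d_d = np.linalg.norm(voxels[sl] - det, axis=-1)
        d_di = np.linalg.norm(_mirror(voxels[sl], zb) - det, axis=-1)
        g_s = _free_kernel(d_s, tq, props) - _free_kernel(d_si, tq, props)
        g_d = _free_kernel(d_d, t - tq, props) - _free_kernel(d_di, t - tq, props)
        out[sl] = props.v * np.einsum("ij,ij->i", g_s, g_d) * dt
    return out


# ---------------------------------------------------------------------------
# Closed-form statistical moments of the model curve
# ---------------------------------------------------------------------------


def _raw_time_moments(props: OpticalProperties, rho: float, boundary: str, k_max: int = 4):
    """Raw time moments ∫ t^k R(t) dt, k = 0..k_max, up to a common constant.

    Each image term t^{-3/2} exp(-a/t - b t) integrates to
    2 (a/b)^{(2k-1)/4} K_{(2k-1)/2}(2 sqrt(a b)) with a = r²/(4 D v) and
    b = µa v.
    """
    Dv = props.D * props.v
    b = props.mu_a * props.v
    r_s, r_d = _effective_endpoints(props, rho)
    zb = props.zb(boundary)
    r1 = np.linalg.norm(r_d - r_s)
    r2 = np.linalg.norm(_mirror(r_d, zb) - r_s)
    moments = np.zeros(k_max + 1)
    for sign, r in ((1.0, r1), (-1.0, r2)):
        a = r**2 / (4.0 * Dv)
        x = 2.0 * np.sqrt(a * b)
        for k in range(k_max + 1):
            nu = (2 * k - 1) / 2.0
            moments[k] += sign * 2.0 * (a / b) ** (nu / 2.0) * special.kv(nu, x)
    return moments * (4.0 * np.pi * Dv) ** -1.5


def theoretical_moments(
    props: OpticalProperties, rho: float, boundary: str = "extrapolated"
) -> MomentSet:
    """Moments of the ideal (noise-free, IRF-free) model curve.

    ``N`` is the curve's total time integral in the kernel's arbitrary
    units (only ratios of N are meaningful); m1, V, m3, m4 are in ps^k.
    """
    M = _raw_time_moments(props, rho, boundary)
    if M[0] <= 0:
        raise ValueError("degenerate model curve (non-positive integral)")
    mu = M[1:] / M[0]
    m1 = mu[0]
    V = mu[1] - m1**2
    m3 = mu[2] - 3 * m1 * mu[1] + 2 * m1**3
    m4 = mu[3] - 4 * m1 * mu[2] + 6 * m1**2 * mu[1] - 3 * m1**4
    return MomentSet(float(M[0]), float(m1), float(V), float(m3), float(m4))


def estimate_optical_properties(
    measured: MomentSet,
    irf: MomentSet,
    rho: float,
    n: float = 1.33,
    boundary: str = "extrapolated",
    rtol: float = 1e-6,
) -> tuple[OpticalProperties, dict]:
    """Estimate (µa, µs′) from DTOF moments of a homogeneous medium.

    The instrument response enters the measured DTOF by convolution, under
    which the mean time of flight and the variance add; the IRF moments are
    therefore subtracted (m1_tissue = m1_meas - m1_irf, V_tissue = V_meas -
    V_irf) and the model moments are inverted for the pair (µa, µs′) at the
    given separation by two-dimensional root finding on the closed-form
    moments, seeded by a coarse log-grid scan.

    Returns the fitted properties and a diagnostics dict with the relative
    moment residuals.
    """
    m1_t = measured.m1 - irf.m1
    V_t = measured.V - irf.V
    if V_t <= 0:
        raise ValueError("measured variance does not exceed IRF variance; cannot invert")
    if m1_t <= 0:
        raise ValueError("measured mean time does not exceed IRF mean time; cannot invert")

    def residuals(logp: np.ndarray) -> np.ndarray:
        props = OpticalProperties(np.exp(logp[0]), np.exp(logp[1]), n=n)
        mom = theoretical_moments(props, rho, boundary)
        return np.array([mom.m1 / m1_t - 1.0, mom.V / V_t - 1.0])

    # coarse scan for a starting point, then Levenberg-Marquardt refinement
    mua_grid = np.exp(np.linspace(np.log(0.01), np.log(1.0), 10))
    musp_grid = np.exp(np.linspace(np.log(2.0), np.log(60.0), 12))
    best, best_cost = None, np.inf
    for mua in mua_grid:
        for musp in musp_grid:
            r = residuals(np.log([mua, musp]))
            cost = float(r @ r)
            if cost < best_cost:
                best, best_cost = np.log([mua, musp]), cost
    sol = optimize.least_squares(residuals, best, xtol=rtol, ftol=rtol, gtol=rtol)
    res = residuals(sol.x)
    if not sol.success or np.max(np.abs(res)) > 1e-3:
        raise RuntimeError(
            f"moment inversion did not converge: residuals {res}, status {sol.status}"
        )
    props = OpticalProperties(float(np.exp(sol.x[0])), float(np.exp(sol.x[1])), n=n)
    return props, {"residuals": res, "cost": float(sol.cost), "nfev": int(sol.nfev)}
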