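"""Depth profiles, depth selectivity, photon-noise models, and S×CNR.

Depth-related sensitivity is obtained by collapsing a 3-D Δ-moment map
over the transverse axes (Y then X), leaving a column along depth Z.
Depth selectivity S_M is the ratio of the summed sensitivity within a
deep layer to that within an equally thick superficial layer; because the
inclusion's Δµa is common to every voxel it cancels in the ratio.

Photon noise of the moment measurands follows the standard counting
statistics of a DTOF with N detected photons:

    σ²(N)  = N,
    σ²(m1) = V / N,
    σ²(V)  = (m4 - V²) / N,

and propagates through the subtraction geometries as

    σ²_SS = σ²_SD,far + σ²_SD,near,
    σ²_DS = σ²_SS / 2          (DS averages two SS measurements),

so σ_DS/σ_SS = 1/√2.  The contrast-to-noise ratio CNR_M divides the
deep-layer summed sensitivity by σ(M0), and the overall performance of a
method/moment pair is the product

    S_M × CNR_M = (Σ_lower ΔM)² / (σ(M0) · Σ_upper ΔM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dtof import MomentSet, moments_from_counts, truncation_window
from .pipeline import SensitivityMap3D

__all__ = [
    "DepthProfile",
    "SelectivityCurve",
    "NoiseModel",
    "PerformanceScore",
    "depth_profile",
    "depth_selectivity",
    "photon_noise_sd",
    "empirical_noise_sd",
    "overall_performance",
]


@dataclass(frozen=True)
class DepthProfile:
    """Layer-summed sensitivity along depth, raw and normalized.

    ``normalized`` divides by the layer of maximal |sum|, preserving sign,
    so its largest magnitude is 1 (when any layer is nonzero).
    """

    depth_mm: np.ndarray
    layer_sums: np.ndarray
    normalized: np.ndarray
    moment: str
    method: str


@dataclass(frozen=True)
class SelectivityCurve:
    """Depth selectivity S_M versus the start depth of the lower layer."""

    z_start_mm: np.ndarray
    S: np.ndarray  # NaN where the upper-layer sum vanishes
    layer_thickness_mm: float
    moment: str
    method: str


@dataclass(frozen=True)
class NoiseModel:
    """Photon-noise standard deviations of (N, m1, V) per geometry.

    ``sd_far``/``sd_near`` are the single-distance sigmas (σ_N, σ_m1, σ_V)
    of the far and near channels; ``ss``/``ds`` follow from error
    propagation.  ``source`` records whether the sigmas are theoretical
    (counting statistics) or empirical (replication scatter).

    The sensitivity maps store the attenuation change ΔA = -ln(N_i/N_0)
    rather than ΔN, so the noise of the *measurand* for moment "A" is
    σ(A) = σ(N)/N = 1/√N; :meth:`measurand_sigma` performs that
    conversion (m1 and V are stored in their native units and need none).
    """

    sd_far: np.ndarray  # (σ_N, σ_m1, σ_V)
    sd_near: np.ndarray
    n_far: float
    n_near: float
    source: str = "theoretical"

    @property
    def ss(self) -> np.ndarray:
        return np.sqrt(self._meas(self.sd_far, self.n_far) ** 2
                       + self._meas(self.sd_near, self.n_near) ** 2)

    @property
    def ds(self) -> np.ndarray:
        return self.ss / np.sqrt(2.0)

    @staticmethod
    def _meas(sd: np.ndarray, n: float) -> np.ndarray:
        return np.array([sd[0] / n, sd[1], sd[2]])

    def sigma(self, method: str, moment: str) -> float:
        """Measurand sigma (A dimensionless, m1 ps, V ps²) per geometry."""
        idx = {"A": 0, "m1": 1, "V": 2}[moment]
        if method.startswith("SD"):
            return float(self._meas(self.sd_far, self.n_far)[idx])
        if method.startswith("SS"):
            return float(self.ss[idx])
        if method == "DS":
            return float(self.ds[idx])
        raise ValueError(f"unknown method {method!r}")

    measurand_sigma = sigma


@dataclass(frozen=True)
class PerformanceScore:
    """Depth selectivity, CNR, and their product for one map and noise model.

    The product is reported as a magnitude with its sign stored separately,
    since a negative selectivity (deep and superficial sensitivities of
    opposite sign) is meaningful but magnitude comparisons are customary.
    """

    moment: str
    method: str
    top_thickness_mm: float
    selectivity: float
    cnr: float
    product: float  # |S × CNR|
    product_sign: float
    sigma: float


def _layer_sums(map3d: SensitivityMap3D) -> tuple[np.ndarray, np.ndarray]:
    """Depth coordinates (mm) and the per-Z-layer sums over X and Y."""
    sums = map3d.values.sum(axis=(0, 2))
    return map3d.grid.z_mm.copy(), sums


def depth_profile(map3d: SensitivityMap3D, layer_thickness_mm: Optional[float] = None) -> DepthProfile:
    """Depth-related sensitivity: sums within Z layers, normalized.

    By default each grid plane is its own layer (thickness = Z step);
    thicker layers group consecutive planes.  Normalization divides by the
    layer of maximal absolute sum, preserving sign.
    """
    z, sums = _layer_sums(map3d)
    dz = float(z[1] - z[0]) if z.size > 1 else 1.0
    if layer_thickness_mm is not None and z.size > 1:
        per = max(1, int(round(layer_thickness_mm / dz)))
        n_layers = z.size // per
        z = np.array([z[i * per : (i + 1) * per].mean() for i in range(n_layers)])
        sums = np.array([sums[i * per : (i + 1) * per].sum() for i in range(n_layers)])
    peak = np.max(np.abs(sums)) if sums.size else 0.0
    if peak == 0.0:
        warnings.warn("all-zero sensitivity map; depth profile left unnormalized")
        normalized = sums.copy()
    else:
        normalized = sums / peak
    return DepthProfile(z, sums, normalized, map3d.moment, map3d.method)


def _slab_sum(z: np.ndarray, sums: np.ndarray, start: float, thickness_layers: int) -> float:
    """Sum of ``thickness_layers`` consecutive layer sums starting at the
    first plane at depth >= start."""
    idx = int(np.searchsorted(z, start - 1e-9))
    if idx + thickness_layers > z.size:
        raise ValueError("slab extends beyond the deepest grid plane")
    return float(sums[idx : idx + thickness_layers].sum())


def depth_selectivity(
    map3d: SensitivityMap3D,
    z_starts_mm: Optional[np.ndarray] = None,
    thickness_layers: int = 3,
) -> SelectivityCurve:
    """Depth selectivity versus lower-layer start depth.

    The upper layer starts at the surface (shallowest grid plane) and the
    lower layer at each ``z_starts_mm``; both span ``thickness_layers``
    consecutive grid planes (3 planes of a 2 mm grid ≈ the customary
    ≈5 mm slab).  Points where the upper-layer sum vanishes are reported
    as NaN rather than infinity.
    """
    z, sums = _layer_sums(map3d)
    dz = float(z[1] - z[0]) if z.size > 1 else 1.0
    if z_starts_mm is None:
        z_max = z[-1] - (thickness_layers - 1) * dz
        z_starts_mm = np.arange(5.0, min(30.0, z_max) + 1e-9, dz)
    z_starts_mm = np.asarray(z_starts_mm, dtype=float)
    upper = _slab_sum(z, sums, z[0], thickness_layers)
    S = np.empty(z_starts_mm.size)
    for i, z0 in enumerate(z_starts_mm):
        lower = _slab_sum(z, sums, z0, thickness_layers)
        S[i] = np.nan if upper == 0.0 else lower / upper
    thickness_mm = thickness_layers * dz
    return SelectivityCurve(z_starts_mm, S, thickness_mm, map3d.moment, map3d.method)


def photon_noise_sd(far: MomentSet, near: MomentSet) -> NoiseModel:
    """Theoretical photon-noise sigmas from baseline far/near moments."""
    sigmas = []
    for m in (far, near):
        if m.N <= 0:
            raise ValueError("photon noise undefined for zero total counts")
        var_v = m.m4 - m.V**2
        if var_v < 0:
            raise ValueError("m4 < V**2: inconsistent moment set")
        sigmas.append(np.array([np.sqrt(m.N), np.sqrt(m.V / m.N), np.sqrt(var_v / m.N)]))
    return NoiseModel(
        sd_far=sigmas[0], sd_near=sigmas[1], n_far=far.N, n_near=near.N,
        source="theoretical",
    )


def empirical_noise_sd(
    curve: np.ndarray,
    t: np.ndarray,
    total_counts: float,
    n_replications: int,
    rng,
    truncation_fraction: float = 0.01,
) -> np.ndarray:
    """Monte-Carlo sigmas (σ_N, σ_m1, σ_V) of Poisson replications.

    The truncation window is frozen from the expected curve and applied to
    every replication, so the replication moments are pure matrix
    operations; the corresponding theoretical sigmas should be evaluated
    on the same window.
    """
    if np.isscalar(rng) or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    curve = np.asarray(curve, dtype=float)
    lo, hi = truncation_window(curve, truncation_fraction)
    lam = curve * (total_counts / curve.sum())
    draws = rng.poisson(lam[lo:hi], size=(n_replications, hi - lo)).astype(float)
    m = moments_from_counts(t[lo:hi], draws)
    return np.array([np.std(m.N, ddof=1), np.std(m.m1, ddof=1), np.std(m.V, ddof=1)])


def overall_performance(
    map3d: SensitivityMap3D,
    noise: NoiseModel,
    top_thickness_mm: float = 15.0,
) -> PerformanceScore:
    """Product of depth selectivity and CNR for one map.

    The upper (superficial) slab spans the surface down to
    ``top_thickness_mm`` — chosen at ≈15 mm as an upper bound on adult
    scalp-plus-skull thickness — and the lower slab spans the rest of the
    mapped depth.  CNR divides the lower-slab Δ-moment sum by the
    photon-noise sigma of the measurand for the map's geometry, and

        S × CNR = (Σ_lower ΔM)² / (σ(M0) · Σ_upper ΔM).
    """
    z, sums = _layer_sums(map3d)
    upper = float(sums[z <= top_thickness_mm].sum())
    lower = float(sums[z > top_thickness_mm].sum())
    sigma = noise.sigma(map3d.method, map3d.moment)
    cnr = lower / sigma
    if upper == 0.0:
        warnings.warn("upper-slab sum is zero; selectivity undefined")
        sel = np.nan
        product = np.nan
        sign = np.nan
    else:
        sel = lower / upper
        signed = sel * cnr
        product = abs(signed)
        sign = float(np.sign(signed)) if signed != 0 else 0.0
    return PerformanceScore(
        moment=map3d.moment,
        method=map3d.method,
        top_thickness_mm=top_thickness_mm,
        selectivity=sel,
        cnr=cnr,
        product=product,
        product_sign=sign,
        sigma=sigma,
    )
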