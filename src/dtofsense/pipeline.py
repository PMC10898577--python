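"""From DTOF stacks to Δ-moment sensitivity maps (SD, SS, DS).

For each absorber position i and channel, the change of each statistical
moment relative to the homogeneous baseline is

    ΔA    = -ln(N_i / N_0)          (attenuation change),
    Δ⟨t⟩  = ⟨t⟩_0 - ⟨t⟩_i,
    ΔV    = V_0 - V_i.

Single subtraction (SS) removes the superficial contribution by
subtracting the near-channel Δ-moment from the far-channel Δ-moment of
the same source; dual subtraction (DS) averages the two SS values of the
left and right sources, symmetrizing the sensitivity volume:

    ΔM_SS,left  = ΔM_left,2  - ΔM_left,1
    ΔM_SS,right = ΔM_right,1 - ΔM_right,2
    ΔM_DS       = (ΔM_SS,left + ΔM_SS,right) / 2.

Placing the Δ-moments of all absorber positions on the sweep raster
yields one 3-D sensitivity map per method and moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dtof import MomentSet, moments_from_counts, truncation_window
from .phantom import SweepDataset, SweepGrid

__all__ = [
    "MOMENT_NAMES",
    "METHOD_NAMES",
    "PerturbationDelta",
    "SubtractionResult",
    "SensitivityMap3D",
    "delta_moments",
    "single_subtraction",
    "dual_subtraction",
    "assemble_maps",
]

MOMENT_NAMES = ("A", "m1", "V")
METHOD_NAMES = ("SD_far_left", "SD_far_right", "SS_left", "SS_right", "DS")


@dataclass(frozen=True)
class PerturbationDelta:
    """Δ-moments of one channel at one absorber position.

    dA dimensionless, d_m1 in ps, dV in ps².  ``kind`` records the channel
    or derived method the delta belongs to ("far"/"near" single-distance
    channels, "SS", "DS").
    """

    dA: float
    d_m1: float
    dV: float
    kind: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.dA, self.d_m1, self.dV])


@dataclass(frozen=True)
class SubtractionResult:
    """SS deltas for both sources and their DS average at one position."""

    ss_left: PerturbationDelta
    ss_right: PerturbationDelta
    ds: PerturbationDelta


@dataclass
class SensitivityMap3D:
    """Δ-moment values on the sweep raster for one method and moment.

    ``values`` has shape (nx, nz, ny) matching the grid axes; masked
    (missing) positions hold NaN.  Dividing by the inclusion's Δµa yields
    the sensitivity-factor (SF) map; that division cancels in depth
    selectivity, so maps store the raw Δ-moment by default and record any
    applied division in ``delta_mu_a``.
    """

    values: np.ndarray
    grid: SweepGrid
    moment: str  # "A" | "m1" | "V"
    method: str  # one of METHOD_NAMES
    delta_mu_a: Optional[float] = None

    def __post_init__(self) -> None:
        if self.moment not in MOMENT_NAMES:
            raise ValueError(f"unknown moment {self.moment!r}")
        if self.method not in METHOD_NAMES:
            raise ValueError(f"unknown method {self.method!r}")
        if self.values.shape != self.grid.shape:
            raise ValueError("map shape does not match grid shape")

    def as_sf(self, delta_mu_a: float) -> "SensitivityMap3D":
        """Sensitivity-factor map: Δ-moment per unit inclusion Δµa."""
        return SensitivityMap3D(
            self.values / delta_mu_a, self.grid, self.moment, self.method, delta_mu_a
        )

    def plane_sum(self, axis: str) -> np.ndarray:
        """Projection by summation over one axis ('x', 'z' or 'y')."""
        return self.values.sum(axis={"x": 0, "z": 1, "y": 2}[axis])


def delta_moments(
    baseline: MomentSet, perturbed: MomentSet, log_base: str = "e", kind: str = ""
) -> PerturbationDelta:
    """Δ-moments of a perturbed DTOF relative to the homogeneous baseline.

    ``log_base`` selects the attenuation logarithm ("e" natural, "10"
    decadic); the natural log is the convention of the moments literature
    and the default.
    """
    if perturbed.N <= 0 or baseline.N <= 0:
        raise ValueError("total counts must be positive to form an attenuation change")
    ratio = perturbed.N / baseline.N
    if log_base == "e":
        dA = -np.log(ratio)
    elif log_base in ("10", 10):
        dA = -np.log10(ratio)
    else:
        raise ValueError(f"unknown log base {log_base!r}")
    return PerturbationDelta(
        dA=float(dA),
        d_m1=float(baseline.m1 - perturbed.m1),
        dV=float(baseline.V - perturbed.V),
        kind=kind,
    )


def single_subtraction(
    delta_far: PerturbationDelta, delta_near: PerturbationDelta
) -> PerturbationDelta:
    """Far-channel minus near-channel Δ-moments for one source."""
    if delta_far.kind and delta_near.kind and delta_far.kind == delta_near.kind:
        raise ValueError(
            "single subtraction needs one far and one near channel, got two "
            f"{delta_far.kind!r} inputs"
        )
    return PerturbationDelta(
        dA=delta_far.dA - delta_near.dA,
        d_m1=delta_far.d_m1 - delta_near.d_m1,
        dV=delta_far.dV - delta_near.dV,
        kind="SS",
    )


def dual_subtraction(
    ss_left: PerturbationDelta, ss_right: PerturbationDelta
) -> PerturbationDelta:
    """Component-wise mean of the two single-subtraction deltas."""
    return PerturbationDelta(
        dA=0.5 * (ss_left.dA + ss_right.dA),
        d_m1=0.5 * (ss_left.d_m1 + ss_right.d_m1),
        dV=0.5 * (ss_left.dV + ss_right.dV),
        kind="DS",
    )


def _stack_moments(
    t: np.ndarray,
    counts: np.ndarray,
    truncation_fraction: float,
    drop_first: int,
    n_average: int,
    window: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Per-position (N, m1, V) after replicate averaging and truncation.

    ``counts`` has shape (n_pos, n_rep, n_bins); returns (n_pos, 3).  With
    ``window`` given, that fixed bin range is applied to every position;
    otherwise the window is recomputed per averaged DTOF.
    """
    use = counts[:, drop_first : drop_first + n_average, :].mean(axis=1)
    if window is not None:
        lo, hi = window
        m = moments_from_counts(t[lo:hi], use[:, lo:hi])
        return np.column_stack([m.N, m.m1, m.V])
    out = np.empty((use.shape[0], 3))
    for i, row in enumerate(use):
        lo, hi = truncation_window(row, truncation_fraction)
        m = moments_from_counts(t[lo:hi], row[lo:hi])
        out[i] = (m.N, m.m1, m.V)
    return out


def assemble_maps(
    dataset: SweepDataset,
    truncation_fraction: float = 0.01,
    log_base: str = "e",
    drop_first: Optional[int] = None,
    n_average: Optional[int] = None,
    baseline_mode: str = "reference",
    truncation_mode: str = "baseline",
) -> dict[tuple[str, str], SensitivityMap3D]:
    """Assemble all (method, moment) sensitivity maps from a sweep dataset.

    Replicate handling mirrors the acquisition protocol: of the recorded
    replicates the first ``drop_first`` (taken during absorber motion) are
    discarded and the next ``n_average`` averaged.  Defaults drop the
    first half when 20 or more replicates are present, otherwise use all.

    ``truncation_mode``: with "baseline" (default) the 1% tail-cut window
    is determined once per channel from its baseline DTOF and applied
    identically to every absorber position, so that baseline and perturbed
    moments are differenced over the same support; "per-position"
    recomputes the window for every averaged DTOF.  The frozen window
    avoids discrete one-bin window jumps, which otherwise dominate the
    small deep-layer Δ-moments after subtraction.

    ``baseline_mode``: "reference" uses the absorber-absent recordings;
    "outermost" emulates the experimental convention of averaging the
    positions on the outermost X planes of the sweep instead.

    Returns a dict keyed by (method, moment), methods being the two far
    single-distance channels, the two single subtractions, and the dual
    subtraction.
    """
    n_rep = dataset.n_replicates
    if drop_first is None or n_average is None:
        if n_rep >= 20:
            drop_first, n_average = 10, 10
        else:
            drop_first, n_average = 0, n_rep
    if drop_first + n_average > n_rep:
        raise ValueError("drop_first + n_average exceeds available replicates")

    t = dataset.time_grid.centers
    geom = dataset.geometry
    grid = dataset.grid

    if truncation_mode not in ("baseline", "per-position"):
        raise ValueError(f"unknown truncation_mode {truncation_mode!r}")

    deltas: dict[str, np.ndarray] = {}  # channel -> (n_pos, 3) [dA, d_m1, dV]
    for ch in geom.channels:
        base_counts = dataset.baselines[ch][drop_first : drop_first + n_average].mean(
            axis=0
        )
        lo, hi = truncation_window(base_counts, truncation_fraction)
        window = (lo, hi) if truncation_mode == "baseline" else None
        per_pos = _stack_moments(
            t, dataset.channels[ch], truncation_fraction, drop_first, n_average,
            window=window,
        )
        if baseline_mode == "reference":
            bm = moments_from_counts(t[lo:hi], base_counts[lo:hi])
            base = np.array([bm.N, bm.m1, bm.V])
        elif baseline_mode == "outermost":
            nx, nz, ny = grid.shape
            cube = per_pos.reshape(nx, nz, ny, 3)
            base = cube[[0, -1]].mean(axis=(0, 1, 2))
        else:
            raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
        log = np.log if log_base == "e" else np.log10
        dA = -log(per_pos[:, 0] / base[0])
        d_m1 = base[1] - per_pos[:, 1]
        dV = base[2] - per_pos[:, 2]
        deltas[ch] = np.column_stack([dA, d_m1, dV])

    ss_left = deltas["left_2"] - deltas["left_1"]
    ss_right = deltas["right_1"] - deltas["right_2"]
    ds = 0.5 * (ss_left + ss_right)
    method_values = {
        "SD_far_left": deltas["left_2"],
        "SD_far_right": deltas["right_1"],
        "SS_left": ss_left,
        "SS_right": ss_right,
        "DS": ds,
    }

    maps: dict[tuple[str, str], SensitivityMap3D] = {}
    for method, vals in method_values.items():
        for j, moment in enumerate(MOMENT_NAMES):
            maps[(method, moment)] = SensitivityMap3D(
                values=vals[:, j].reshape(grid.shape),
                grid=grid,
                moment=moment,
                method=method,
            )
    return maps
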