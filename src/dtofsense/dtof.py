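"""Distributions of times of flight (DTOFs) and their statistical moments.

A DTOF is the histogram of photon arrival delays recorded by a
time-correlated single-photon-counting channel: photon counts per time bin
on a uniform picosecond grid.  The analysis methods in this package operate
on the first few statistical moments of the DTOF:

* ``N`` — total number of photons (0th moment, proportional to intensity),
* ``m1`` — mean time of flight ⟨t⟩ (ps),
* ``V`` — centralized variance of the DTOF (ps²),

plus the centralized third and fourth moments needed by the photon-noise
model.  Before moments are computed, both tails of the histogram are cut
where the counts drop below a fraction (default 1%) of the histogram
maximum, which stabilises the higher moments against dark counts and
late-tail noise.

Counts are real-valued throughout: averaged DTOFs are non-integer, and the
Poisson interpretation of counts enters only in the noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DTOF",
    "MomentSet",
    "truncate_dtof",
    "truncation_window",
    "compute_moments",
    "moments_from_counts",
    "average_dtofs",
]


@dataclass(frozen=True)
class DTOF:
    """One photon time-of-flight histogram for one source-detector channel.

    Parameters
    ----------
    bin_centers:
        Bin center times in picoseconds, strictly increasing, uniformly
        spaced.
    counts:
        Non-negative photon counts per bin (real-valued).
    channel_id:
        Free-form channel label, e.g. ``"left_2"`` for the left source and
        detector 2.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    channel_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.bin_centers, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size or t.size == 0:
            raise ValueError("bin_centers and counts must be equal-length 1-D arrays")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("bin_centers must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("bin_centers must be uniformly spaced")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.isfinite(c)):
            raise ValueError("counts must be finite")
        object.__setattr__(self, "bin_centers", t)
        object.__setattr__(self, "counts", c)

    @property
    def bin_width(self) -> float:
        """Bin width in ps (grid spacing; 0 is impossible for >=2 bins)."""
        if self.bin_centers.size < 2:
            return 0.0
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def with_counts(self, counts: np.ndarray) -> "DTOF":
        return replace(self, counts=np.asarray(counts, dtype=float))


@dataclass(frozen=True)
class MomentSet:
    """Statistical moments of a (truncated) DTOF.

    ``N`` is the total count, ``m1`` the mean time of flight (ps), ``V`` the
    centralized variance (ps²), and ``m3``/``m4`` the centralized third and
    fourth moments (ps³, ps⁴) used by the photon-noise model.
    """

    N: float
    m1: float
    V: float
    m3: float = 0.0
    m4: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.m1, self.V, self.m3, self.m4])


def truncation_window(counts: np.ndarray, threshold_fraction: float = 0.01) -> tuple[int, int]:
    """Half-open index range ``[lo, hi)`` retained by the tail cut.

    Scans outward from the global maximum on each side and cuts at the
    FIRST bin whose counts fall strictly below
    ``threshold_fraction * max(counts)``; bins exactly at the threshold are
    retained.  Scanning outward (rather than inward from the edges) is
    robust to noisy re-crossings in the tails.
    """
    c = np.asarray(counts, dtype=float)
    cmax = c.max() if c.size else 0.0
    if cmax <= 0:
        raise ValueError("cannot truncate an all-zero DTOF")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    thr = threshold_fraction * cmax
    imax = int(np.argmax(c))
    lo = imax
    while lo > 0 and c[lo - 1] >= thr:
        lo -= 1
    hi = imax + 1
    while hi < c.size and c[hi] >= thr:
        hi += 1
    return lo, hi


def truncate_dtof(dtof: DTOF, threshold_fraction: float = 0.01) -> DTOF:
    """Cut both DTOF tails where counts drop below 1% (default) of the peak.

    Returns the contiguous bin range around the global maximum bounded on
    each side by the first bin, moving outward, whose counts fall strictly
    below ``threshold_fraction`` times the maximum.  Idempotent: truncating
    a truncated DTOF returns it unchanged.
    """
    lo, hi = truncation_window(dtof.counts, threshold_fraction)
    return replace(dtof, bin_centers=dtof.bin_centers[lo:hi], counts=dtof.counts[lo:hi])


def compute_moments(dtof: DTOF) -> MomentSet:
    """Total count, mean time of flight, and centralized moments 2-4.

    Operates on the histogram as given; the pipeline truncates first.
    """
    return moments_from_counts(dtof.bin_centers, dtof.counts)


def moments_from_counts(t: np.ndarray, counts: np.ndarray) -> MomentSet:
    """Moments of count rows over bin centers ``t``.

    ``counts`` may be 1-D (one DTOF) or 2-D ``(n_rows, n_bins)`` for batched
    evaluation over a shared, already-truncated window; the 2-D form returns
    a MomentSet of arrays.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(counts, dtype=float)
    N = c.sum(axis=-1)
    if np.any(N <= 0):
        raise ValueError("moments undefined for zero total counts")
    m1 = (c * t).sum(axis=-1) / N
    d = t - (m1[..., None] if c.ndim == 2 else m1)
    V = (c * d**2).sum(axis=-1) / N
    m3 = (c * d**3).sum(axis=-1) / N
    m4 = (c * d**4).sum(axis=-1) / N
    if c.ndim == 1:
        return MomentSet(float(N), float(m1), float(V), float(m3), float(m4))
    return MomentSet(N, m1, V, m3, m4)


def average_dtofs(dtofs: Sequence[DTOF]) -> DTOF:
    """Bin-wise arithmetic mean of DTOFs sharing one bin grid and channel."""
    if not dtofs:
        raise ValueError("need at least one DTOF to average")
    first = dtofs[0]
    for d in dtofs[1:]:
        if d.bin_centers.shape != first.bin_centers.shape or not np.allclose(
            d.bin_centers, first.bin_centers
        ):
            raise ValueError("all DTOFs must share the same bin grid")
        if d.channel_id != first.channel_id:
            raise ValueError("all DTOFs must come from the same channel")
    mean = np.mean([d.counts for d in dtofs], axis=0)
    return first.with_counts(mean)
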