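# Methods

This note records the models implemented in `dtofsense`, their
assumptions, the defaults and why they were chosen, and what the
synthetic phantom does and does not establish about real measurements.

## Forward model

Light transport in the homogeneous semi-infinite medium (z > 0) is
described by the diffusion approximation with

* diffusion coefficient `D = 1/(3 µs′)` (absorption-independent
  convention, the one used throughout the DTOF-moments literature),
* energy speed `v = c/n`, default `n = 1.33` (water-based phantom),
* extrapolated-boundary condition: the fluence vanishes on the plane
  `z = −z_b`, `z_b = 2AD`, with the internal-reflection parameter `A(n)`
  from the Groenhuis/Egan approximation (`A ≈ 2.79` at n = 1.33). A
  zero-boundary option (`z_b = 0`) exists for comparison.

The Green's function is the free diffusion kernel minus its negative
image about the extrapolated plane. The detected time-resolved signal for
a source-detector pair is modeled as this kernel evaluated between an
effective source point and an effective detector point, each buried one
transport mean free path `z0 = 1/µs′` below the surface. This fluence-kernel
detection model was chosen over the Fick (flux, `t^{-5/2}`) form because it
makes three relations exact rather than approximate, and the package's
consistency checks rely on all three:

1. absorption enters every curve only through `exp(−µa v t)`;
2. the kernel obeys the Chapman–Kolmogorov semigroup property, so the
   Born absorption Jacobian is the time convolution of the
   source-to-voxel and voxel-to-detector kernels,
   `ΔR(t) = −Δµa·ΔV·v·(G_s ⊛ G_d)(t)`;
3. the voxel-volume integral of the Jacobian at arrival time t equals
   `v·t·R(t)` — the mean total pathlength of photons detected at time t
   is exactly `v·t`.

The two model forms share the same late-time asymptotics and differ only
in a mild early-time reweighting; since every quantity the package
reports is either a ratio, a difference against a baseline computed with
the same model, or a self-consistency check, the choice does not affect
any conclusion.

Statistical moments of the model curve have closed forms: each image term
`t^{-3/2} exp(−a/t − bt)` (with `a = r²/4Dv`, `b = µa v`) integrates
against `t^k` to `2(a/b)^{(2k−1)/4} K_{(2k−1)/2}(2√(ab))`. These closed
forms agree with adaptive quadrature to better than 0.1% (tested) and are
the inner loop of property estimation.

## Optical-property estimation

Convolution adds means and variances, so the instrument response
function's `m1` and `V` are subtracted from the measured moments, and the
closed-form model moments are inverted for `(µa, µs′)` at the known
separation by Levenberg–Marquardt on log-parameters (relative tolerance
1e-6), seeded by a coarse log-grid scan over µa ∈ [0.01, 1] cm⁻¹ and
µs′ ∈ [2, 60] cm⁻¹. The scan makes the inversion insensitive to the
starting point across the scattering range studied (µs′ 5–20 cm⁻¹).
Estimation uses untruncated moments (the 1% tail cut is a mapping-stage
convention; applying it to the measured but not the model moments would
bias the inversion). Degenerate inputs — measured variance or mean time
not exceeding the IRF's — raise immediately.

## Synthetic phantom

The simulator emulates a tank experiment: a homogeneous milk/ink liquid
(defaults µa = 0.1 cm⁻¹, µs′ = 10 cm⁻¹), two sources at ±27.5 mm and two
detectors at ±2.5 mm on the surface line (far separation 30 mm, near
25 mm), and a small absorbing cylinder (3 mm diameter, 5 mm height)
stepped over a 75 × 35 × 20 mm cuboid in 2/2/1 mm steps (X/Z/Y), the
absorber centroid starting 2 mm below the surface. Per position and
channel the perturbed curve is the baseline plus the Born Jacobian times
`−Δµa·ΔV`, floored at zero; it is then convolved with a unit-integral
Gaussian IRF (default FWHM 650 ps, the midpoint of the 595–717 ps range
typical of hybrid-PMT TCSPC systems), scaled to the photon budget, and
sampled with per-bin Poisson noise for each replicate.

Defaults that mirror the acquisition protocol:

* photon budget: 3.5×10⁶ counts/s per detector (summed over its two
  source channels), 0.09 s collection per replicate; the budget is split
  between the far and near channel of each detector in proportion to the
  model curve integrals;
* 20 replicates per position, of which the analysis drops the first 10
  (recorded during absorber motion) and averages the next 10;
* inclusion strength: Δµa = 0.1 cm⁻¹ over the cylinder volume
  (0.035 cm³), calibrated once so the peak attenuation change on the far
  channel is ≈0.1 — comfortably inside the linear (Born) regime.

What the phantom does *not* capture: a physically black absorber is far
beyond linear perturbation theory (its measured contrast saturates), the
real IRF is asymmetric, and instrument drift and physiological noise are
absent. Passing tests therefore establish the correctness and internal
consistency of the analysis chain and the *directional* structure of the
sensitivity maps (sign patterns, peak-depth ordering, method rankings) —
not the absolute magnitudes a physical absorber would produce.

### Dead time

With interleaved lasers, the two DTOFs a detector records share its
counting electronics, so the dead time triggered by one channel's photons
removes counting capacity from the other (intensity cross-talk). This is
modeled as non-paralyzable, rate-driven uniform scaling:
`m_A = n_A/(1 + n_B τ/T)` and symmetrically, with τ the per-event dead
time and T the acquisition time. The coupled pair inverts in closed form,
so correction after application is exact to round-off. Real dead time
also distorts the DTOF shape (pile-up); only the counting-loss scaling is
modeled, which is the part that produces the cross-channel attenuation
artifact the correction targets.

## Analysis conventions

* **Truncation.** Both DTOF tails are cut at the first bin, scanning
  outward from the global maximum, whose counts fall strictly below 1% of
  the maximum; bins exactly at the threshold are retained. Scanning
  outward is robust to noisy re-crossings in the tails. In the map
  pipeline the window is determined once per channel from the baseline
  DTOF and applied identically to every absorber position
  (`truncation_mode="baseline"`): recomputing it per position makes the
  window jump by whole bins as the perturbation moves, and those discrete
  jumps dominate the genuinely small deep-layer Δ-moments after
  subtraction. A `per-position` mode is available for data whose baseline
  shape drifts.
* **Attenuation logarithm.** Natural log by default (`log_base="10"`
  available, recorded in outputs).
* **Baseline.** Absorber-absent recordings by default; an `outermost`
  mode reproduces the experimental convention of using the sweep's
  outermost X planes, and agrees with the reference baseline to <1% when
  those planes are ≥3 separations from the optodes (tested).
* **Maps.** Stored as (X, Z, Y) arrays on the sweep raster with explicit
  axis coordinates; the sweep enumerates Y fastest, then Z, then X.
* **Depth profiles.** Z-layer sums over the full X/Y extent, normalized
  by the layer of maximal absolute sum with sign preserved.
* **Depth selectivity.** `S(Z)` divides the sum over 3 consecutive
  2 mm planes starting at depth Z (≈5 mm slab; a 2-plane option exists)
  by the same-thickness slab at the surface, for Z from 5 to 30 mm.
  Δµa of the inclusion cancels in the ratio. A vanishing superficial
  slab yields NaN, not infinity.
* **Noise.** σ(M0) uses the theoretical counting-statistics model on the
  baseline moments by default (an empirical replication mode exists and
  agrees within 5% at 10⁶ counts, tested). Because the maps store
  `ΔA = −ln(N_i/N_0)` rather than ΔN, the measurand sigma for the 0th
  moment is `σ(N)/N = 1/√N`; m1 and V need no conversion. Single-distance
  scores use the far-channel sigma.
* **S×CNR.** The superficial slab spans the surface to 15 mm (an upper
  bound on adult scalp-plus-skull thickness), the deep slab the rest of
  the mapped depth. Sums are signed; the score reports |S×CNR| with the
  sign stored separately, since a negative selectivity is meaningful but
  magnitude comparisons are customary.

## Behavior on the default synthetic phantom

On the noiseless reduced sweep at the default optics the package
reproduces the expected directional structure (all tested): single-distance
ΔA is non-negative everywhere and peaks superficially, Δ⟨t⟩ and ΔV are
negative in near-surface voxels between the optodes with positive maxima
deeper; peak layer depth orders A ≤ m1 ≤ V within each method and DS ≥ SD
per moment; SS and DS depth profiles coincide (exactly, by the symmetry
of the geometry); DS S×CNR exceeds SD's for every moment with variance
highest; and across µs′ ∈ {5, 10, 20} cm⁻¹ the SD peak depth is
non-increasing and the peak contrast non-decreasing. One Born-model
particular: the DS superficial negative lobe for m1/V extends to ≈8 mm
depth — thicker than in a physical phantom with a saturating absorber —
so the DS selectivity curve is negative at every evaluated start depth
for m1 but turns negative for V only once the deep slab clears that lobe
(Z ≳ 7 mm); the acceptance test asserts negativity from 10 mm on.

For a homogeneous global absorption step of +0.005 cm⁻¹, the single
subtraction retains ≈19% of the single-distance ΔA at this geometry
(3 vs 2.5 cm); the residual reflects the genuine difference in total
pathlength between the two separations and shrinks as the separations
approach each other.

## Problem sizes

The default sweep raster (38 × 18 × 21 positions, 4096-bin curves, 20
replicates) matches the experimental protocol and is practical for
production runs. The test suite and the acceptance script use reduced
rasters — 16 × 18 × 5 positions at 4/2/3 mm steps with 1024-bin curves
for the directional analyses, 10 × 8 × 5 for the voxel-wise Born
consistency check, a 13k-voxel dense grid for the pathlength identity,
and 10⁴ Poisson replications for the noise model — sizes at which every
reported quantity is already converged to well inside its test tolerance.

## Known limitations

* Born-level perturbation only: strong absorbers (the "black" cylinder of
  real phantoms) saturate and are deliberately not reproduced in
  magnitude; the simulator warns when a configured perturbation removes
  >50% of a curve's mass.
* Homogeneous semi-infinite media only — no layered or heterogeneous
  optics, no Monte-Carlo transport, no frequency-domain quantities.
* No IRF deconvolution (moments are handled additively instead), no
  in-vivo physiological noise, no vendor TCSPC file readers.
* The moment inversion assumes the diffusion model is exact; at short
  separations or very low scattering the diffusion approximation itself
  biases the recovered coefficients.
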