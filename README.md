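# dtofsense

Depth-selective analysis of time-domain near-infrared diffuse reflectance
(td-NIRS), built around the statistical moments of photon time-of-flight
distributions (DTOFs) and the dual-subtraction measurement geometry.

## The problem

In td-NIRS, picosecond laser pulses are launched into a scattering medium
(tissue, or a liquid phantom) and the arrival-time histogram of detected
photons — the DTOF — is recorded a few centimetres away. Absorption changes
in the medium alter the DTOF's statistical moments:

* `N_tot` — total photon count (0th moment, ≙ intensity), reported as the
  attenuation change `ΔA = −ln(N_i/N_0)`;
* `⟨t⟩` — mean time of flight (1st moment), `Δ⟨t⟩ = ⟨t⟩_0 − ⟨t⟩_i`;
* `V` — variance of the DTOF (2nd centralized moment), `ΔV = V_0 − V_i`.

Signals from the superficial layer (scalp and skull, in brain monitoring)
contaminate all of these. The **single-subtraction** (SS) method suppresses
superficial contributions by differencing a far (3 cm) and a near (2.5 cm)
channel sharing one source; the **dual-subtraction** (DS) method places two
sources symmetrically around a closely spaced detector pair and averages
the two single subtractions:

    ΔM_SS,left  = ΔM_left,2 − ΔM_left,1
    ΔM_SS,right = ΔM_right,1 − ΔM_right,2
    ΔM_DS       = (ΔM_SS,left + ΔM_SS,right) / 2

This package implements the full analysis chain — DTOF moments with 1%
tail truncation, Δ-moment sensitivity maps per method, depth-related
sensitivity profiles, depth selectivity `S_M` (deep-slab over
superficial-slab summed sensitivity), the photon-noise model

    σ²(N) = N,   σ²(m1) = V/N,   σ²(V) = (m4 − V²)/N,
    σ²_SS = σ²_far + σ²_near,    σ²_DS = σ²_SS / 2,

and the overall-performance score `S_M × CNR_M = (Σ_lower ΔM)² /
(σ(M0)·Σ_upper ΔM)` — together with the pieces needed to exercise it with
no instrument: a semi-infinite diffusion forward model (extrapolated
boundary, Born absorption Jacobian, closed-form curve moments,
moment-based estimation of µa and µs′) and a synthetic liquid-phantom
simulator that steps a small absorbing cylinder through a cuboid raster,
broadens with the instrument response function, applies Poisson counting
noise, and optionally emulates dead-time cross-talk between the
interleaved laser channels.

It is intended for researchers in diffuse optics who want to prototype or
validate depth-selective measurement geometries and measurands before (or
alongside) phantom and in-vivo experiments.

## Worked example

`examples/03_depth_selectivity.py` simulates a noiseless sweep of the
default phantom (µa = 0.1 cm⁻¹, µs′ = 10 cm⁻¹, separations 3/2.5 cm) and
prints:

```
SD_far_left: depth of maximal layer sensitivity
  A  : z = 4 mm, superficial layer value +0.98
  m1 : z = 10 mm, superficial layer value +0.06
  V  : z = 12 mm, superficial layer value -0.02

DS: depth of maximal layer sensitivity
  A  : z = 8 mm, superficial layer value +0.41
  m1 : z = 12 mm, superficial layer value -0.41
  V  : z = 16 mm, superficial layer value -0.23

depth selectivity S(Z) at Z = 15 mm (5-ish mm slabs):
  SD_far_left  A  : S = +0.062
  SD_far_left  m1 : S = +0.743
  SD_far_left  V  : S = +2.995
  DS           A  : S = +0.277
  DS           m1 : S = -1.959
  DS           V  : S = -2.835
```

Reading: the depth of maximal sensitivity grows with the moment order and
is deeper for the dual subtraction than for the single-distance method;
DS is nearly insensitive (slightly negative) to superficial absorption
changes for `m1` and `V`, which is its purpose, and its selectivity for
those moments is negative because superficial and deep changes pull the
measurand in opposite directions. `examples/04_noise_and_performance.py`
adds the noise model and shows the S×CNR ranking (DS beats SD for every
moment; the variance scores highest within each method).

The other examples cover the forward model with optical-property recovery
(`01`) and raw sensitivity-map assembly (`02`). A thin CLI wraps the same
library calls for batch use:

```
dtofsense simulate --config run.toml --out sweep.h5
dtofsense analyze --dataset sweep.h5 --config run.toml --out analysis/
```

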