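"""Time-resolved reflectance of a semi-infinite milk/ink phantom and
moment-based recovery of its optical properties.

Builds the model curve at a 3 cm source-detector separation, prints its
statistical moments, then convolves it with a realistic instrument
response and inverts the moments back to (µa, µs′)."""

import numpy as np

from dtofsense import OpticalProperties, TimeGrid, estimate_optical_properties, reflectance_td
from dtofsense.dtof import moments_from_counts
from dtofsense.forward import theoretical_moments
from dtofsense.phantom import apply_irf, gaussian_irf

props = OpticalProperties(mu_a=0.098, mu_s_prime=10.13)  # estimated phantom values
grid = TimeGrid(t_stop=10_000.0, n_bins=2048)

curve = reflectance_td(props, rho=3.0, grid=grid)
m = theoretical_moments(props, 3.0)
print(f"model moments at 3 cm: <t> = {m.m1:.1f} ps, V = {m.V:.0f} ps^2")
# mean time of flight ~1 ns: photons travel ~22 cm through the liquid.

irf = gaussian_irf(grid, fwhm_ps=650.0, t0_ps=1000.0)
measured = apply_irf(curve, irf, grid.dt)
meas_m = moments_from_counts(grid.centers, measured)
print(f"with IRF broadening:  <t> = {meas_m.m1:.1f} ps, V = {meas_m.V:.0f} ps^2")
# convolution adds the IRF's mean delay and variance to the DTOF's.

est, info = estimate_optical_properties(
    meas_m, moments_from_counts(grid.centers, irf), rho=3.0
)
print(
    f"recovered optics: mu_a = {est.mu_a:.4f} cm^-1, mu_s' = {est.mu_s_prime:.2f} cm^-1"
    f"  (true: {props.mu_a}, {props.mu_s_prime})"
)
# subtracting the IRF moments and inverting the model recovers both
# coefficients to well under a percent in the noiseless limit.
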