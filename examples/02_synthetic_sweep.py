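"""Simulate an absorber sweep and assemble Δ-moment sensitivity maps.

A small absorbing cylinder is stepped through a reduced raster of the
default phantom; the four-channel DTOFs are analyzed into single-distance
(SD), single-subtraction (SS) and dual-subtraction (DS) maps of the three
statistical moments."""

import numpy as np

from dtofsense import (
    Inclusion,
    NoiseConfig,
    OpticalProperties,
    OptodeGeometry,
    SweepGrid,
    TimeGrid,
    simulate_sweep,
)
from dtofsense.pipeline import assemble_maps

grid = SweepGrid.from_extents(
    x_extent_mm=60, x_step_mm=4, z_extent_mm=34, z_step_mm=2,
    y_extent_mm=12, y_step_mm=3, z_start_mm=2,
)
dataset = simulate_sweep(
    OpticalProperties(0.1, 10.0), OptodeGeometry(), grid, Inclusion(),
    NoiseConfig(poisson=False), seed=0, time_grid=TimeGrid(10_000.0, 1024),
    n_replicates=1,
)
print(f"simulated {grid.n_positions} absorber positions on a {grid.shape} raster")

maps = assemble_maps(dataset)
for method in ("SD_far_left", "SS_left", "DS"):
    peak_dA = np.max(np.abs(maps[(method, "A")].values))
    print(f"{method:12s} peak |dA| = {peak_dA:.4f}")
# the subtraction methods trade peak contrast for depth selectivity: the
# DS attenuation contrast is smaller than SD's but localized deeper.

ds_m1 = maps[("DS", "m1")].values
ix, iz, iy = np.unravel_index(np.argmax(ds_m1), ds_m1.shape)
print(
    f"DS mean-time sensitivity peaks at x={grid.x_mm[ix]:.0f} mm, "
    f"z={grid.z_mm[iz]:.0f} mm (under the detector pair, well below the surface)"
)
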