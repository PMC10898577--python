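"""Validated run configuration (TOML or YAML).

All lengths in configuration files are millimetres and all times
picoseconds; optics coefficients are cm⁻¹.  Conversions to the cm/ps
internal units happen when the configuration is turned into model
objects.  Unknown keys are rejected so typos fail loudly, and the fully
resolved configuration (defaults applied) is embedded in every output
artifact.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .forward import OpticalProperties, OptodeGeometry, TimeGrid
from .phantom import DeadTimeModel, Inclusion, NoiseConfig, SweepGrid

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsSection(_Strict):
    mu_a: float = Field(0.1, gt=0, description="absorption coefficient, cm^-1")
    mu_s_prime: float = Field(10.0, gt=0, description="reduced scattering, cm^-1")
    n: float = Field(1.33, ge=1.0, description="refractive index")


class GeometrySection(_Strict):
    far_separation_mm: float = Field(30.0, gt=0)
    near_separation_mm: float = Field(25.0, gt=0)

    @field_validator("near_separation_mm")
    @classmethod
    def _near_lt_far(cls, v, info):
        far = info.data.get("far_separation_mm")
        if far is not None and v >= far:
            raise ValueError("near separation must be smaller than far separation")
        return v


class GridSection(_Strict):
    x_extent_mm: float = Field(75.0, gt=0)
    x_step_mm: float = Field(2.0, gt=0)
    z_extent_mm: float = Field(35.0, gt=0)
    z_step_mm: float = Field(2.0, gt=0)
    y_extent_mm: float = Field(20.0, gt=0)
    y_step_mm: float = Field(1.0, gt=0)
    z_start_mm: float = Field(2.0, gt=0)


class InclusionSection(_Strict):
    diameter_mm: float = Field(3.0, gt=0)
    height_mm: float = Field(5.0, gt=0)
    delta_mu_a: float = Field(0.1, gt=0, description="effective Born-level Δµa, cm^-1")


class NoiseSection(_Strict):
    count_rate_per_detector: float = Field(3.5e6, gt=0)
    collection_time_s: float = Field(0.09, gt=0)
    irf_fwhm_ps: float = Field(650.0, gt=0)
    irf_t0_ps: float = Field(1000.0, ge=0)
    poisson: bool = True
    deadtime_tau_ns: Optional[float] = Field(None, ge=0)
    seed: int = 0
    n_replicates: int = Field(20, ge=1)


class TimeGridSection(_Strict):
    t_stop_ps: float = Field(10_000.0, gt=0)
    n_bins: int = Field(4096, ge=16)


class AnalysisSection(_Strict):
    log_base: str = Field("e", pattern="^(e|10)$")
    truncation_fraction: float = Field(0.01, gt=0, lt=1)
    selectivity_thickness_layers: int = Field(3, ge=1)
    top_thickness_mm: float = Field(15.0, gt=0)
    noise_source: str = Field("theoretical", pattern="^(theoretical|empirical)$")
    baseline_mode: str = Field("reference", pattern="^(reference|outermost)$")


class RunConfig(_Strict):
    """Full resolved configuration of a simulate/analyze run."""

    optics: OpticsSection = OpticsSection()
    geometry: GeometrySection = GeometrySection()
    grid: GridSection = GridSection()
    inclusion: InclusionSection = InclusionSection()
    noise: NoiseSection = NoiseSection()
    time_grid: TimeGridSection = TimeGridSection()
    analysis: AnalysisSection = AnalysisSection()

    # -- conversions to model objects (mm -> cm where needed) ---------------

    def optical_properties(self) -> OpticalProperties:
        o = self.optics
        return OpticalProperties(o.mu_a, o.mu_s_prime, o.n)

    def optode_geometry(self) -> OptodeGeometry:
        g = self.geometry
        return OptodeGeometry(g.far_separation_mm / 10.0, g.near_separation_mm / 10.0)

    def sweep_grid(self) -> SweepGrid:
        g = self.grid
        return SweepGrid.from_extents(
            g.x_extent_mm, g.x_step_mm, g.z_extent_mm, g.z_step_mm,
            g.y_extent_mm, g.y_step_mm, g.z_start_mm,
        )

    def inclusion_model(self) -> Inclusion:
        i = self.inclusion
        return Inclusion(i.diameter_mm, i.height_mm, i.delta_mu_a)

    def noise_config(self) -> NoiseConfig:
        n = self.noise
        deadtime = DeadTimeModel(n.deadtime_tau_ns, n.collection_time_s) if n.deadtime_tau_ns else None
        return NoiseConfig(
            count_rate_per_detector=n.count_rate_per_detector,
            collection_time_s=n.collection_time_s,
            irf_fwhm_ps=n.irf_fwhm_ps,
            irf_t0_ps=n.irf_t0_ps,
            poisson=n.poisson,
            deadtime=deadtime,
        )

    def time_grid_model(self) -> TimeGrid:
        return TimeGrid(self.time_grid.t_stop_ps, self.time_grid.n_bins)

    def resolved_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a TOML or YAML configuration; None gives defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text) or {}
    else:
        data = tomllib.loads(text)
    return RunConfig.model_validate(data)
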