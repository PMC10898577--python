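"""HDF5 containers for sweep datasets and sensitivity maps, CSV exports.

Container layout (versioned via /meta/schema_version):

    /channels/{name}/dtofs      (position, replicate, bin) counts
    /channels/{name}/positions  (position, 3) absorber centroid XYZ in mm
    /baseline/{name}            (replicate, bin) absorber-absent counts
    /meta                       attributes: schema_version, config (JSON),
                                seed, time-grid and geometry scalars
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import OpticalProperties, OptodeGeometry, TimeGrid
from .metrics import DepthProfile, PerformanceScore, SelectivityCurve
from .phantom import SweepDataset, SweepGrid
from .pipeline import SensitivityMap3D

SCHEMA_VERSION = "dtofsense-sweep-1"

__all__ = [
    "SCHEMA_VERSION",
    "write_sweep",
    "read_sweep",
    "write_maps",
    "read_maps",
    "positions_manifest",
    "profiles_frame",
    "selectivity_frame",
    "performance_frame",
]


def write_sweep(dataset: SweepDataset, path: str | Path, config_json: str = "{}") -> None:
    path = Path(path)
    positions = dataset.grid.positions_mm()
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["config"] = config_json
        meta.attrs["metadata"] = json.dumps(dataset.metadata)
        meta.attrs["t_stop_ps"] = dataset.time_grid.t_stop
        meta.attrs["t_start_ps"] = dataset.time_grid.t_start
        meta.attrs["n_bins"] = dataset.time_grid.n_bins
        meta.attrs["far_separation_cm"] = dataset.geometry.far_separation
        meta.attrs["near_separation_cm"] = dataset.geometry.near_separation
        meta.attrs["mu_a"] = dataset.props.mu_a
        meta.attrs["mu_s_prime"] = dataset.props.mu_s_prime
        meta.attrs["n_medium"] = dataset.props.n
        meta.create_dataset("x_mm", data=dataset.grid.x_mm)
        meta.create_dataset("z_mm", data=dataset.grid.z_mm)
        meta.create_dataset("y_mm", data=dataset.grid.y_mm)
        ch_grp = f.create_group("channels")
        for name, stack in dataset.channels.items():
            g = ch_grp.create_group(name)
            g.create_dataset("dtofs", data=stack)
            g.create_dataset("positions", data=positions)
        base = f.create_group("baseline")
        for name, stack in dataset.baselines.items():
            base.create_dataset(name, data=stack)


def read_sweep(path: str | Path) -> SweepDataset:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise ValueError(f"{path}: missing /meta group; not a sweep container")
        meta = f["meta"]
        version = meta.attrs.get("schema_version", "")
        if version != SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported schema {version!r}")
        grid = SweepGrid(meta["x_mm"][:], meta["z_mm"][:], meta["y_mm"][:])
        time_grid = TimeGrid(
            float(meta.attrs["t_stop_ps"]),
            int(meta.attrs["n_bins"]),
            float(meta.attrs["t_start_ps"]),
        )
        geometry = OptodeGeometry(
            float(meta.attrs["far_separation_cm"]),
            float(meta.attrs["near_separation_cm"]),
        )
        props = OpticalProperties(
            float(meta.attrs["mu_a"]),
            float(meta.attrs["mu_s_prime"]),
            float(meta.attrs["n_medium"]),
        )
        metadata = json.loads(meta.attrs.get("metadata", "{}"))
        for group in ("channels", "baseline"):
            if group not in f:
                raise ValueError(f"{path}: missing /{group} group")
        channels = {name: f["channels"][name]["dtofs"][:] for name in f["channels"]}
        baselines = {name: f["baseline"][name][:] for name in f["baseline"]}
    return SweepDataset(
        time_grid=time_grid,
        grid=grid,
        geometry=geometry,
        props=props,
        channels=channels,
        baselines=baselines,
        metadata=metadata,
    )


def write_maps(maps: dict[tuple[str, str], SensitivityMap3D], path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION + "-maps"
        first = next(iter(maps.values()))
        f.create_dataset("x_mm", data=first.grid.x_mm)
        f.create_dataset("z_mm", data=first.grid.z_mm)
        f.create_dataset("y_mm", data=first.grid.y_mm)
        for (method, moment), m in maps.items():
            d = f.create_dataset(f"maps/{method}/{moment}", data=m.values)
            d.attrs["axes"] = "x,z,y"


def read_maps(path: str | Path) -> dict[tuple[str, str], SensitivityMap3D]:
    path = Path(path)
    out: dict[tuple[str, str], SensitivityMap3D] = {}
    with h5py.File(path, "r") as f:
        grid = SweepGrid(f["x_mm"][:], f["z_mm"][:], f["y_mm"][:])
        for method in f["maps"]:
            for moment in f["maps"][method]:
                out[(method, moment)] = SensitivityMap3D(
                    f["maps"][method][moment][:], grid, moment, method
                )
    return out


def positions_manifest(grid: SweepGrid) -> pd.DataFrame:
    pos = grid.positions_mm()
    return pd.DataFrame(
        {"index": np.arange(pos.shape[0]), "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2]}
    )


def profiles_frame(profiles: list[DepthProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for z, raw, norm in zip(p.depth_mm, p.layer_sums, p.normalized):
            rows.append(
                {"method": p.method, "moment": p.moment, "z_mm": z,
                 "layer_sum": raw, "normalized": norm}
            )
    return pd.DataFrame(rows)


def selectivity_frame(curves: list[SelectivityCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for z, s in zip(c.z_start_mm, c.S):
            rows.append(
                {"method": c.method, "moment": c.moment, "z_start_mm": z,
                 "S": s, "layer_thickness_mm": c.layer_thickness_mm}
            )
    return pd.DataFrame(rows)


def performance_frame(scores: list[PerformanceScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": s.method,
                "moment": s.moment,
                "selectivity": s.selectivity,
                "cnr": s.cnr,
                "product": s.product,
                "product_sign": s.product_sign,
                "sigma": s.sigma,
                "top_thickness_mm": s.top_thickness_mm,
            }
            for s in scores
        ]
    )
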