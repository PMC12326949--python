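"""Readers and writers for the gridded-cube and index-table formats.

Cubes are CF-like NetCDF files with dims (time, lat, lon), ``units`` /
``long_name`` attributes and NaN fill at masked cells; teleconnection
indices travel as a CSV with an ISO year-month ``time`` column and one
column per mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .preprocess import IndexSeries, MonthlyGrid
from .synthetic import TCM_NAMES, PlantedPathway, World, WorldConfig

__all__ = ["write_cubes", "read_cube", "write_indices", "read_indices",
           "write_fixture", "read_fixture"]

KNOWN_TCMS = set(TCM_NAMES)


def _grid_to_dataarray(grid: MonthlyGrid) -> xr.DataArray:
    nlat, nlon = grid.mask.shape
    da = xr.DataArray(
        grid.values,
        dims=("time", "lat", "lon"),
        coords={
            "time": grid.time.to_timestamp(),
            "lat": np.arange(nlat, dtype=float),
            "lon": np.arange(nlon, dtype=float),
        },
        attrs={"units": grid.units, "long_name": grid.name,
               "variable_role": grid.variable_role},
    )
    return da


def write_cubes(grids: dict[str, MonthlyGrid], path, mask: np.ndarray | None = None) -> Path:
    """Write one or more MonthlyGrids (sharing a time axis) to a NetCDF file."""
    path = Path(path)
    data = {name: _grid_to_dataarray(g) for name, g in grids.items()}
    ds = xr.Dataset(data)
    if mask is not None:
        ds["burnable_mask"] = xr.DataArray(mask.astype(np.int8), dims=("lat", "lon"))
    ds.to_netcdf(path)
    ds.close()
    return path


def read_cube(path, var: str | None = None):
    """Read MonthlyGrid(s) back; validates the monthly time axis.

    Returns a dict name -> MonthlyGrid (plus the mask if stored), or a
    single grid when ``var`` is given.
    """
    with xr.open_dataset(Path(path)) as ds:
        if "time" not in ds.coords:
            raise ValueError(f"{path}: no time coordinate")
        time = pd.PeriodIndex(pd.DatetimeIndex(ds["time"].values), freq="M")
        if len(time) > 1:
            steps = np.diff(time.asi8)
            if not np.all(steps == 1):
                gaps = time[1:][steps != 1]
                raise ValueError(f"{path}: non-monthly cadence or missing months before {list(gaps[:3])}")
        if "burnable_mask" in ds:
            mask = ds["burnable_mask"].values.astype(bool)
        else:
            first = next(v for v in ds.data_vars if v != "burnable_mask")
            mask = np.isfinite(ds[first].values).any(axis=0)
        out = {}
        for name, da in ds.data_vars.items():
            if name == "burnable_mask":
                continue
            vals = da.values.astype(float)
            if not np.isfinite(vals).any():
                raise ValueError(f"{path}:{name}: variable is all-NaN")
            out[name] = MonthlyGrid(
                vals, time, mask, name=str(da.attrs.get("long_name", name)),
                units=str(da.attrs.get("units", "")),
                variable_role=str(da.attrs.get("variable_role", "other")),
            )
    if var is not None:
        return out[var]
    return out


def write_indices(indices: list[IndexSeries], path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time": indices[0].time.astype(str)})
    for s in indices:
        df[s.name] = s.values
    df.to_csv(path, index=False, float_format="%.17g")  # exact float64 round-trip
    return path


def read_indices(path) -> list[IndexSeries]:
    """Read the TCM index table; unknown columns are carried with a warning."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path}: no 'time' column")
    time = pd.PeriodIndex(df["time"], freq="M")
    out = []
    for col in df.columns:
        if col == "time":
            continue
        if col not in KNOWN_TCMS:
            warnings.warn(f"unknown index column {col!r}; carried through", stacklevel=2)
        vals = df[col].to_numpy(dtype=float)
        if not np.isfinite(vals).any():
            raise ValueError(f"{path}:{col}: index column is all-NaN")
        out.append(IndexSeries(vals, time, col))
    return out


def write_fixture(world: World, path) -> Path:
    """Persist a synthetic world (cubes + index CSV + config JSON) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    grids = dict(world.mediators)
    grids["BA"] = world.ba
    write_cubes(grids, path / "cubes.nc", mask=world.mask)
    write_indices(world.indices, path / "indices.csv")
    cfg = asdict(world.config)
    cfg["burnable_mask"] = world.mask.astype(int).tolist()
    cfg["grid_shape"] = list(world.config.grid_shape)
    cfg["mediator_names"] = list(world.config.mediator_names)
    cfg["pathway_specs"] = [asdict(p) for p in world.config.pathway_specs]
    with open(path / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=1)
    return path


def read_fixture(path) -> World:
    path = Path(path)
    with open(path / "config.json") as fh:
        cfg = json.load(fh)
    cfg["burnable_mask"] = np.asarray(cfg["burnable_mask"], dtype=bool)
    cfg["grid_shape"] = tuple(cfg["grid_shape"])
    cfg["mediator_names"] = tuple(cfg["mediator_names"])
    cfg["pathway_specs"] = [
        PlantedPathway(**{**p, "region": tuple(tuple(r) for r in p["region"])})
        for p in cfg["pathway_specs"]
    ]
    config = WorldConfig(**cfg)
    grids = read_cube(path / "cubes.nc")
    ba = grids.pop("BA")
    indices = read_indices(path / "indices.csv")
    return World(config, indices, grids, ba, list(config.pathway_specs))
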