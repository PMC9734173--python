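"""File interchange: netCDF velocity fields, GeoJSON domains, CSV matrices.

Velocity fields are CF-style netCDF (variables ``u``/``v`` with dims
``time, depth, y, x``, units m s-1, time in hours since the window start),
written through xarray's scipy backend (NetCDF3, no compiled netCDF library
required). Domains travel as a GeoJSON FeatureCollection of reef polygons
plus a JSON descriptor for grid, mask and region table. Connectivity
matrices are CSV with region names as header row/column in north→south
order, or a single netCDF cube (year × source × sink) for a whole stack.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .ocean import Domain, VelocityField
from .connectivity import ConnectivityMatrix, ConnectivityStack

__all__ = [
    "write_velocity_netcdf",
    "read_velocity_netcdf",
    "write_domain_geojson",
    "read_domain_geojson",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_stack_netcdf",
    "read_stack_netcdf",
    "plot_matrix",
]

_ENGINE = "scipy"


def write_velocity_netcdf(field: VelocityField, path) -> None:
    ds = xr.Dataset(
        {
            "u": (("time", "depth", "y", "x"), field.u, {"units": "m s-1", "long_name": "eastward current"}),
            "v": (("time", "depth", "y", "x"), field.v, {"units": "m s-1", "long_name": "northward current"}),
        },
        coords={
            "time": ("time", field.time_hours, {"units": "hours since window start"}),
            "depth": ("depth", field.depths, {"units": "m", "positive": "down"}),
            "y": ("y", field.grid_y, {"units": "km", "long_name": "northward coordinate"}),
            "x": ("x", field.grid_x, {"units": "km", "long_name": "eastward coordinate"}),
        },
        attrs={
            "index_value": float(field.index_value),
            "seed": -1 if field.seed is None else int(field.seed),
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_velocity_netcdf(path) -> VelocityField:
    # time is relative hours since the window start, not a calendar axis
    with xr.open_dataset(path, engine=_ENGINE, decode_times=False) as ds:
        ds.load()
    for var in ("u", "v"):
        if var not in ds:
            raise ValueError(f"{path}: missing variable '{var}'")
        if ds[var].dims != ("time", "depth", "y", "x"):
            raise ValueError(f"{path}: variable '{var}' has dims {ds[var].dims}, "
                             "expected (time, depth, y, x)")
    return VelocityField(
        u=ds["u"].values.astype(np.float32),
        v=ds["v"].values.astype(np.float32),
        time_hours=ds["time"].values.astype(float),
        depths=ds["depth"].values.astype(float),
        grid_x=ds["x"].values.astype(float),
        grid_y=ds["y"].values.astype(float),
        index_value=float(ds.attrs.get("index_value", np.nan)),
        seed=None if ds.attrs.get("seed", -1) == -1 else int(ds.attrs["seed"]),
    )


def write_domain_geojson(domain: Domain, geojson_path, descriptor_path) -> None:
    Path(geojson_path).write_text(json.dumps(domain.to_geojson_dict()))
    Path(descriptor_path).write_text(json.dumps(domain.to_descriptor_dict()))


def read_domain_geojson(geojson_path, descriptor_path) -> Domain:
    gj = json.loads(Path(geojson_path).read_text())
    meta = json.loads(Path(descriptor_path).read_text())
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{geojson_path}: not a GeoJSON FeatureCollection")
    return Domain.from_geojson_dicts(gj, meta)


def write_matrix_csv(matrix: ConnectivityMatrix, path, decimals: int = 10) -> None:
    matrix.to_dataframe().round(decimals).to_csv(path, index_label="source")


def read_matrix_csv(path, year: int = 0, region_ids=None) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col="source")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape})")
    if region_ids is None:
        region_ids = list(range(1, df.shape[0] + 1))
    return ConnectivityMatrix.from_dataframe(df, year=year, region_ids=list(region_ids))


def write_stack_netcdf(stack: ConnectivityStack, path) -> None:
    names = stack.matrices[0].region_names or [str(i) for i in stack.region_ids]
    ds = xr.Dataset(
        {"connectivity": (("year", "source", "sink"), stack.as_array())},
        coords={
            "year": stack.years,
            "source": ("source", np.asarray(stack.region_ids)),
            "sink": ("sink", np.asarray(stack.region_ids)),
        },
        attrs={"region_names": json.dumps(list(map(str, names)))},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_stack_netcdf(path) -> ConnectivityStack:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    if "connectivity" not in ds:
        raise ValueError(f"{path}: missing variable 'connectivity'")
    names = json.loads(ds.attrs.get("region_names", "[]"))
    rids = [int(r) for r in ds["source"].values]
    mats = [
        ConnectivityMatrix(
            year=int(y),
            values=ds["connectivity"].values[k],
            region_ids=rids,
            region_names=names,
        )
        for k, y in enumerate(ds["year"].values)
    ]
    return ConnectivityStack(mats)


def plot_matrix(matrix: ConnectivityMatrix, ax=None, log: bool = True, cmap: str = "viridis"):
    """Minimal heat-map of a connectivity matrix (convenience only)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    vals = matrix.values
    norm = None
    if log:
        pos = vals[np.isfinite(vals) & (vals > 0)]
        if pos.size:
            norm = LogNorm(vmin=pos.min(), vmax=pos.max())
    im = ax.imshow(np.ma.masked_invalid(vals), cmap=cmap, norm=norm)
    ax.set_xlabel("sink region (north → south)")
    ax.set_ylabel("source region (north → south)")
    ax.set_title(f"connectivity {matrix.year}")
    ax.figure.colorbar(im, ax=ax, label="probability")
    return ax
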