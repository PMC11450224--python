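"""netCDF / CSV serialization.

Gridded fields travel as CF-style netCDF (dimensions time/lat/lon, with
units attributes) written through xarray's scipy backend; station series
as flat CSV with columns station_id, lon, lat, date, value, valid_flag.
Every pipeline stage can be re-run from these serialized artifacts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec
from .synthetic import Landscape, MeteoFields, StationNetwork
from .transport import ConcentrationField

_ENGINE = "scipy"


def _coords(grid: GridSpec) -> dict:
    return {"lat": ("lat", grid.lat_centers), "lon": ("lon", grid.lon_centers)}


def grid_from_dataset(ds: xr.Dataset) -> GridSpec:
    lat = ds["lat"].values
    lon = ds["lon"].values
    dlat = float(lat[1] - lat[0])
    dlon = float(lon[1] - lon[0])
    return GridSpec(
        lon_min=float(lon[0] - dlon / 2), lon_max=float(lon[-1] + dlon / 2),
        lat_min=float(lat[0] - dlat / 2), lat_max=float(lat[-1] + dlat / 2),
        nx=len(lon), ny=len(lat),
    )


def concentration_to_dataset(conc: ConcentrationField) -> xr.Dataset:
    return xr.Dataset(
        {"concentration": (("time", "lat", "lon"), conc.values, {"units": "grains m-3"})},
        coords={"time": conc.times, **_coords(conc.grid)},
        attrs={"Conventions": "CF-1.8"},
    )


def dataset_to_concentration(ds: xr.Dataset) -> ConcentrationField:
    return ConcentrationField(
        grid=grid_from_dataset(ds),
        times=pd.DatetimeIndex(ds["time"].values),
        values=ds["concentration"].values,
    )


def field2d_to_dataset(field: np.ndarray, grid: GridSpec, name: str, units: str = "1") -> xr.Dataset:
    return xr.Dataset(
        {name: (("lat", "lon"), field, {"units": units})},
        coords=_coords(grid),
        attrs={"Conventions": "CF-1.8"},
    )


def write_netcdf(ds: xr.Dataset, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine=_ENGINE)


def open_netcdf(path: str | Path) -> xr.Dataset:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return ds.load()


def meteo_to_dataset(meteo: MeteoFields) -> xr.Dataset:
    dims = ("time", "lat", "lon")
    return xr.Dataset(
        {
            "T": (dims, meteo.T, {"units": "K"}),
            "u": (dims, meteo.u, {"units": "m s-1"}),
            "v": (dims, meteo.v, {"units": "m s-1"}),
            "wstar": (dims, meteo.wstar, {"units": "m s-1"}),
            "q": (dims, meteo.q, {"units": "%"}),
            "P": (dims, meteo.P, {"units": "mm h-1"}),
        },
        coords={"time": meteo.times, **_coords(meteo.grid)},
        attrs={"Conventions": "CF-1.8", "freq": meteo.freq},
    )


def dataset_to_meteo(ds: xr.Dataset) -> MeteoFields:
    return MeteoFields(
        grid=grid_from_dataset(ds),
        times=pd.DatetimeIndex(ds["time"].values),
        T=ds["T"].values, u=ds["u"].values, v=ds["v"].values,
        wstar=ds["wstar"].values, q=ds["q"].values, P=ds["P"].values,
        freq=str(ds.attrs.get("freq", "D")),
    )


def landscape_to_dataset(ls: Landscape) -> xr.Dataset:
    dims = ("lat", "lon")
    return xr.Dataset(
        {
            "phi": (dims, ls.phi, {"units": "1"}),
            "H_fs": (dims, ls.H_fs, {"units": "K day"}),
            "H_fe": (dims, ls.H_fe, {"units": "K day"}),
            "cell_area": (dims, ls.cell_area_m2, {"units": "m2"}),
        },
        coords=_coords(ls.grid),
        attrs={"Conventions": "CF-1.8"},
    )


def dataset_to_landscape(ds: xr.Dataset) -> Landscape:
    return Landscape(
        grid=grid_from_dataset(ds),
        phi=ds["phi"].values, H_fs=ds["H_fs"].values, H_fe=ds["H_fe"].values,
        cell_area_m2=ds["cell_area"].values,
    )


def stations_to_csv(stations: StationNetwork, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    stations.table.to_csv(path, index=False)


def stations_from_csv(path: str | Path) -> StationNetwork:
    return StationNetwork(table=pd.read_csv(path))


def observations_to_csv(
    obs: dict[str, pd.DataFrame], stations: StationNetwork, path: str | Path
) -> None:
    """Long-format station series: station_id, lon, lat, date, value, valid_flag."""
    meta = stations.table.set_index("station_id")
    frames = []
    for sid, frame in obs.items():
        f = frame.reset_index(names="date")
        f.insert(0, "station_id", sid)
        f.insert(1, "lon", meta.loc[sid, "lon"])
        f.insert(2, "lat", meta.loc[sid, "lat"])
        frames.append(f.rename(columns={"valid": "valid_flag"}))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def observations_from_csv(path: str | Path) -> dict[str, pd.DataFrame]:
    long = pd.read_csv(path, parse_dates=["date"])
    out = {}
    for sid, g in long.groupby("station_id"):
        out[str(sid)] = pd.DataFrame(
            {"value": g["value"].to_numpy(), "valid": g["valid_flag"].to_numpy().astype(bool)},
            index=pd.DatetimeIndex(g["date"]),
        )
    return out


def series_to_csv(series: dict[str, pd.Series], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"station_id": sid, "date": s.index, "value": s.to_numpy()})
        for sid, s in series.items()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def series_from_csv(path: str | Path) -> dict[str, pd.Series]:
    long = pd.read_csv(path, parse_dates=["date"])
    return {
        str(sid): pd.Series(g["value"].to_numpy(), index=pd.DatetimeIndex(g["date"]))
        for sid, g in long.groupby("station_id")
    }
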