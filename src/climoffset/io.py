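"""Readers and writers for the interchange formats.

Dialects
--------
- allele frequencies: wide CSV, first column landrace id, remaining columns
  SNP ids, cells = alternate-allele frequencies in [0, 1], no missing cells;
- landraces / phenotypes: CSV with header (id, lat, lon, country, ...);
- climate grids: either NetCDF (dims ``pixel`` x ``day``, variables precip,
  tmean, tmax, tmin, srad, coords lat/lon) or a long CSV with columns
  (pixel, lat, lon, day, precip, tmean, tmax, tmin, srad);
- metric tables: wide CSV (site id, lat, lon, metric catalog) with a JSON
  manifest naming every metric column;
- turnover models: a single JSON bundle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .climate import ClimateMetricTable, DailyClimateGrid
from .gf import TurnoverModel

CLIMATE_VARS = ("precip", "tmean", "tmax", "tmin", "srad")


# -- allele frequencies ------------------------------------------------------

def write_allele_freqs(freqs: pd.DataFrame, path) -> None:
    freqs.to_csv(path, index_label="id")


def read_allele_freqs(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy()
    if np.isnan(vals.astype(float)).any():
        r, c = np.argwhere(np.isnan(vals.astype(float)))[0]
        raise ValueError(
            f"missing allele frequency at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    bad = np.argwhere((vals < 0) | (vals > 1))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"allele frequency outside [0, 1] at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {vals[r, c]}"
        )
    return df.astype(float)


# -- landraces / phenotypes --------------------------------------------------

def write_landraces(landraces: pd.DataFrame, path) -> None:
    landraces.to_csv(path, index_label="id")


def read_landraces(path) -> pd.DataFrame:
    df = pd.read_csv(path).set_index("id")
    for col in ("lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"landrace table missing column {col!r}")
    if df["lat"].abs().max() > 90:
        bad = df.index[df["lat"].abs() > 90][0]
        raise ValueError(f"invalid latitude for landrace {bad!r}")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index_label="id")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("id")


# -- climate grids -----------------------------------------------------------

def grid_to_dataset(grid: DailyClimateGrid) -> xr.Dataset:
    ds = xr.Dataset(
        {v: (("pixel", "day"), getattr(grid, v)) for v in CLIMATE_VARS},
        coords={"lat": ("pixel", grid.lat), "lon": ("pixel", grid.lon),
                "day": np.arange(grid.n_days)},
        attrs={"period": grid.period, "model": grid.model, "scenario": grid.scenario},
    )
    return ds


def dataset_to_grid(ds: xr.Dataset) -> DailyClimateGrid:
    return DailyClimateGrid(
        lat=ds["lat"].values, lon=ds["lon"].values,
        **{v: ds[v].values for v in CLIMATE_VARS},
        period=str(ds.attrs.get("period", "")),
        model=str(ds.attrs.get("model", "")),
        scenario=str(ds.attrs.get("scenario", "")),
    )


def write_climate_netcdf(grid: DailyClimateGrid, path) -> None:
    grid_to_dataset(grid).to_netcdf(path, engine="scipy")


def read_climate_netcdf(path) -> DailyClimateGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_grid(ds.load())


def write_climate_csv(grid: DailyClimateGrid, path) -> None:
    n_pix, n_days = grid.n_pixels, grid.n_days
    rows = {
        "pixel": np.repeat(np.arange(n_pix), n_days),
        "lat": np.repeat(grid.lat, n_days),
        "lon": np.repeat(grid.lon, n_days),
        "day": np.tile(np.arange(n_days), n_pix),
    }
    for v in CLIMATE_VARS:
        rows[v] = getattr(grid, v).ravel()
    pd.DataFrame(rows).to_csv(path, index=False)


def read_climate_csv(path) -> DailyClimateGrid:
    df = pd.read_csv(path).sort_values(["pixel", "day"])
    pixels = df["pixel"].unique()
    n_days = df["day"].nunique()
    first = df.groupby("pixel").first()
    arrays = {v: df[v].to_numpy(float).reshape(len(pixels), n_days) for v in CLIMATE_VARS}
    return DailyClimateGrid(first["lat"].to_numpy(), first["lon"].to_numpy(), **arrays)


def read_climate(path) -> DailyClimateGrid:
    """Dispatch on extension: .nc -> NetCDF, otherwise the CSV dialect."""
    p = Path(path)
    if p.suffix in {".nc", ".nc4", ".cdf"}:
        return read_climate_netcdf(p)
    return read_climate_csv(p)


# -- metric tables -----------------------------------------------------------

def write_metrics(table: ClimateMetricTable, path, manifest_path=None) -> None:
    table.frame.to_csv(path, index_label="site")
    if manifest_path is not None:
        Path(manifest_path).write_text(
            json.dumps({"metrics": table.metric_names}, indent=1)
        )


def read_metrics(path) -> ClimateMetricTable:
    return ClimateMetricTable(pd.read_csv(path, index_col="site"))


# -- turnover models ---------------------------------------------------------

def write_model(model: TurnoverModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def read_model(path) -> TurnoverModel:
    return TurnoverModel.from_dict(json.loads(Path(path).read_text()))


# -- migration plans ---------------------------------------------------------

def write_plans(plans: pd.DataFrame, path) -> None:
    plans.to_csv(path, index=False)


def plans_to_geojson(plans: pd.DataFrame) -> dict:
    """Migration trajectories as GeoJSON LineString features."""
    features = []
    for _, row in plans.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [
                    [row["focal_lon"], row["focal_lat"]],
                    [row["donor_lon"], row["donor_lat"]],
                ],
            },
            "properties": {
                k: (row[k].item() if hasattr(row[k], "item") else row[k])
                for k in ("model", "cluster", "strategy", "distance_km", "load")
                if k in row
            },
        })
    return {"type": "FeatureCollection", "features": features}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
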