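"""Genomic vulnerability (offset) maps and the common-garden yield validation.

Genomic vulnerability of a location is the Euclidean distance between its
current and future climates after both are passed through the fitted
turnover functions — a proxy for the allele-frequency change the local
population would need to track climate.  Multi-model ensembles are
summarised per pixel by the mean offset, its across-model spread, and a
stippling flag marking pixels where the ensemble agrees (mean more than
twice the population SD, i.e. coefficient of variation below 0.5).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import MultiPoint, Point

from .climate import ClimateMetricTable
from .gf import TurnoverModel

__all__ = [
    "offset",
    "map_offsets",
    "landrace_site_vulnerability",
    "correlate_yield",
    "cultivation_hull",
]

#: CV threshold under which a pixel is stippled (ensemble agreement)
STIPPLE_CV = 0.5


def offset(model: TurnoverModel, x_current, x_future) -> float:
    """Euclidean distance between transformed current and future climates."""
    a = model.transform(x_current)
    b = model.transform(x_future)
    return float(np.linalg.norm(b - a))


def offset_profile(model: TurnoverModel, current: ClimateMetricTable,
                   future: ClimateMetricTable) -> np.ndarray:
    """Vectorised per-site offsets for aligned current/future metric tables."""
    if len(current) != len(future):
        raise ValueError("current and future tables must cover the same sites")
    a = model.transform(current.frame)
    b = model.transform(future.frame)
    return np.linalg.norm(b - a, axis=1)


def cultivation_hull(lat, lon):
    """Convex hull of landrace coordinates delimiting the cultivation area."""
    pts = MultiPoint([(x, y) for x, y in zip(np.asarray(lon, float), np.asarray(lat, float))])
    return pts.convex_hull


def hull_mask(hull, lat, lon) -> np.ndarray:
    """True for pixel centers covered by the hull (boundary inclusive)."""
    return np.array([hull.covers(Point(x, y)) for x, y in zip(lon, lat)])


def map_offsets(
    per_model: dict[str, tuple[TurnoverModel, ClimateMetricTable, ClimateMetricTable]],
    hull=None,
    scenario: str = "",
    horizon: str = "",
) -> pd.DataFrame:
    """Multi-model vulnerability map over the cultivation area.

    ``per_model`` maps each climate-model label to its own fitted turnover
    model and its current/future pixel metric tables (each climate model is
    fitted and predicted separately).  Returns one row per pixel inside the
    hull with per-model offsets, ensemble mean, population SD, CV and the
    stipple flag; the result carries ``scenario``/``horizon`` in ``attrs``.
    """
    if not per_model:
        raise ValueError("need at least one climate model")

    frames = {}
    for label, (model, cur, fut) in per_model.items():
        key = [f"{la:.4f}|{lo:.4f}" for la, lo in zip(cur.lat, cur.lon)]
        s = pd.Series(offset_profile(model, cur, fut), index=key)
        frames[label] = s
        latlon = pd.DataFrame({"lat": cur.lat, "lon": cur.lon}, index=key)

    off = pd.DataFrame(frames)
    if off.isna().any().any():
        n_drop = int(off.isna().any(axis=1).sum())
        warnings.warn(f"dropping {n_drop} pixel(s) missing from at least one model")
        off = off.dropna()
    out = latlon.loc[off.index].copy()

    if hull is not None:
        keep = hull_mask(hull, out["lat"].to_numpy(), out["lon"].to_numpy())
        out, off = out[keep], off[keep]

    vals = off.to_numpy(float)
    out = out.assign(**{f"offset_{m}": off[m] for m in off.columns})
    out["mean"] = vals.mean(axis=1)
    out["sd"] = vals.std(axis=1)  # population SD: fixed model ensemble
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(out["mean"] > 0, out["sd"] / out["mean"], 0.0)
    out["cv"] = cv
    out["stipple"] = out["mean"] > 2.0 * out["sd"]
    out.attrs.update({"scenario": scenario, "horizon": horizon,
                      "models": list(off.columns), "sd_convention": "population"})
    return out.reset_index(drop=True)


def landrace_site_vulnerability(
    model: TurnoverModel,
    origin_metrics: ClimateMetricTable,
    site_metrics: pd.Series,
) -> pd.Series:
    """Per-landrace offset between the climate at its origin and a common
    reference site (e.g. a common-garden trial location)."""
    t_origin = model.transform(origin_metrics.frame)
    t_site = model.transform(site_metrics)
    X = origin_metrics.frame[model.predictors].to_numpy(float)
    oob = (
        (X < model.training_min[model.predictors].to_numpy()).any()
        or (X > model.training_max[model.predictors].to_numpy()).any()
    )
    if oob:
        warnings.warn("some origins lie outside the training metric range; transforms clamped")
    d = np.linalg.norm(t_origin - t_site, axis=1)
    return pd.Series(d, index=origin_metrics.frame.index, name="vulnerability")


def correlate_yield(vuln: pd.Series, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation (r, two-sided p, n) of each yield trait with
    per-landrace genomic vulnerability; pairs with a missing trait value are
    dropped and counted."""
    rows = {}
    for trait in traits.columns:
        pair = pd.concat([vuln, traits[trait]], axis=1, join="inner").dropna()
        if len(pair) < 3:
            raise ValueError(f"trait {trait!r}: fewer than 3 complete pairs")
        y = pair[trait].to_numpy(float)
        if np.ptp(y) == 0:
            raise ValueError(f"trait {trait!r} has zero variance; correlation undefined")
        r, p = stats.pearsonr(pair.iloc[:, 0].to_numpy(float), y)
        rows[trait] = {"r": float(r), "p": float(p), "n": int(len(pair))}
    return pd.DataFrame(rows).T
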