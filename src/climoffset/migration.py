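"""Vulnerable-area detection and assisted-migration planning.

Per climate model, the 10% most vulnerable pixels are clustered by
great-circle DBSCAN; each retained cluster's most vulnerable pixel becomes a
focal site.  A donor pixel is then chosen whose *current* transformed
climate is closest (Euclidean distance in turnover space, "ED") to the
focal site's *future* transformed climate:

- optimal (EDmin): the global ED minimum;
- near-optimal (Closest_EDmin1%): the geographically closest pixel among the
  1% lowest-ED candidates;
- sub-optimal (Closest_EDmin5%): the same with the 5% lowest.

The chosen donor's ED is the migration load — the residual maladaptation of
the migrated variety under the focal site's future climate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .climate import ClimateMetricTable
from .gf import TurnoverModel

EARTH_RADIUS_KM = 6371.0088

STRATEGIES = {"optimal": 0.0, "near_optimal": 0.01, "sub_optimal": 0.05}


def geodesic_km(p1, p2) -> float:
    """Great-circle distance in km between (lat, lon) points in degrees."""
    lat1, lon1 = p1
    lat2, lon2 = p2
    for la in (lat1, lat2):
        if not -90.0 <= la <= 90.0:
            raise ValueError(f"invalid latitude {la}")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geodesic_matrix(lat, lon) -> np.ndarray:
    """Pairwise great-circle distances (km), haversine, vectorised."""
    phi = np.radians(np.asarray(lat, float))
    lmb = np.radians(np.asarray(lon, float))
    dphi = phi[:, None] - phi[None, :]
    dlmb = lmb[:, None] - lmb[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def vulnerable_clusters(
    vmap: pd.DataFrame,
    offset_col: str,
    q: float = 0.90,
    min_pts: int = 4,
    eps_km: float = 300.0,
    merge_km: float = 1200.0,
) -> list[np.ndarray]:
    """Clusters of the most vulnerable pixels of one climate model.

    Pixels with offset at or above the ``q`` quantile are clustered with
    DBSCAN on great-circle distance (``eps_km`` neighbourhood, ``min_pts``
    core threshold); noise pixels are discarded, clusters with fewer than
    ``min_pts`` pixels dropped, and clusters whose focal (most vulnerable)
    pixels lie closer than ``merge_km`` are merged iteratively.  Returns
    index arrays into ``vmap`` rows.
    """
    if eps_km <= 0:
        raise ValueError("eps_km must be positive")
    if len(vmap) < 10:
        raise ValueError("need at least 10 pixels to define a vulnerability quantile")
    off = vmap[offset_col].to_numpy(float)
    thr = np.quantile(off, q)
    vul = np.flatnonzero(off >= thr)
    if vul.size == 0:
        return []
    lat = vmap["lat"].to_numpy(float)[vul]
    lon = vmap["lon"].to_numpy(float)[vul]
    D = geodesic_matrix(lat, lon)
    labels = DBSCAN(eps=eps_km, min_samples=min_pts, metric="precomputed").fit_predict(D)
    clusters = [vul[labels == k] for k in sorted(set(labels)) if k != -1]
    clusters = [c for c in clusters if c.size >= min_pts]
    return _merge_close_clusters(clusters, vmap, offset_col, merge_km)


def _merge_close_clusters(clusters, vmap, offset_col, merge_km):
    """Iteratively merge clusters whose focal pixels are < merge_km apart."""
    clusters = [np.asarray(c) for c in clusters]
    while len(clusters) > 1:
        focals = [focal_pixel(c, vmap, offset_col) for c in clusters]
        pts = [(vmap["lat"].iloc[f], vmap["lon"].iloc[f]) for f in focals]
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = geodesic_km(pts[i], pts[j])
                if d < merge_km and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        merged = np.sort(np.concatenate([clusters[i], clusters[j]]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return [np.sort(c) for c in clusters]


def focal_pixel(cluster: np.ndarray, vmap: pd.DataFrame, offset_col: str) -> int:
    """Most vulnerable pixel of a cluster; ties broken by (lat, lon) order."""
    cluster = np.asarray(cluster)
    if cluster.size == 0:
        raise ValueError("empty cluster")
    off = vmap[offset_col].to_numpy(float)[cluster]
    best = off.max()
    cand = cluster[off == best]
    order = np.lexsort((vmap["lon"].to_numpy(float)[cand], vmap["lat"].to_numpy(float)[cand]))
    return int(cand[order[0]])


def donor_search(
    model: TurnoverModel,
    focal_future: pd.Series,
    candidates_current: ClimateMetricTable,
    strategy: str,
    focal_latlon: tuple[float, float],
    candidate_countries: np.ndarray | None = None,
    focal_country: str | None = None,
    quantile: float | None = None,
) -> dict:
    """Choose the donor pixel for one focal site under one strategy.

    ED_j is the Euclidean distance in turnover space between the focal
    site's future climate and candidate j's current climate, over every
    cultivation pixel (the focal pixel itself included, so self-donation is
    possible).  Ties for the optimal donor go to the geographically nearest,
    then lexicographically smallest, pixel.  Quantile pools for the
    near/sub-optimal strategies are by rank: ceil(n * q) lowest-ED pixels,
    at least 1.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}")
    n = len(candidates_current)
    if n < 2:
        raise ValueError("need at least 2 candidate pixels")

    t_future = model.transform(focal_future)
    t_candidates = model.transform(candidates_current.frame)
    ed = np.linalg.norm(t_candidates - t_future, axis=1)

    lat = candidates_current.lat
    lon = candidates_current.lon
    dist = np.array([geodesic_km(focal_latlon, (la, lo)) for la, lo in zip(lat, lon)])

    q = STRATEGIES[strategy] if quantile is None else quantile
    if strategy == "optimal":
        pool = np.flatnonzero(ed == ed.min())
        # geographic tie-break, then lexicographic
        order = np.lexsort((lon[pool], lat[pool], dist[pool]))
        donor = int(pool[order[0]])
    else:
        k = max(1, math.ceil(n * q))
        pool = np.lexsort((lon, lat, ed))[:k]  # k lowest-ED pixels, stable
        order = np.lexsort((lon[pool], lat[pool], dist[pool]))
        donor = int(pool[order[0]])

    row = {
        "strategy": strategy,
        "donor_index": donor,
        "donor_lat": float(lat[donor]),
        "donor_lon": float(lon[donor]),
        "distance_km": float(dist[donor]),
        "load": float(ed[donor]),
    }
    if candidate_countries is not None:
        row["donor_country"] = candidate_countries[donor]
        row["focal_country"] = focal_country
        row["transboundary"] = bool(candidate_countries[donor] != focal_country)
    return row


def plan_migrations(
    model: TurnoverModel,
    vmap: pd.DataFrame,
    offset_col: str,
    current_metrics: ClimateMetricTable,
    future_metrics: ClimateMetricTable,
    countries: np.ndarray | None = None,
    model_label: str = "model0",
    strategies=("optimal", "near_optimal", "sub_optimal"),
    q: float = 0.90,
    min_pts: int = 4,
    eps_km: float = 300.0,
    merge_km: float = 1200.0,
) -> pd.DataFrame:
    """Full migration plan for one climate model: cluster vulnerable pixels,
    pick focal pixels, and run the donor search per strategy.  ``vmap`` rows,
    ``current_metrics``/``future_metrics`` rows and ``countries`` must align
    pixelwise."""
    clusters = vulnerable_clusters(vmap, offset_col, q=q, min_pts=min_pts,
                                   eps_km=eps_km, merge_km=merge_km)
    rows = []
    for cid, cluster in enumerate(clusters):
        f = focal_pixel(cluster, vmap, offset_col)
        focal_future = future_metrics.frame.iloc[f]
        focal_latlon = (float(vmap["lat"].iloc[f]), float(vmap["lon"].iloc[f]))
        focal_country = countries[f] if countries is not None else None
        for strategy in strategies:
            row = donor_search(
                model, focal_future, current_metrics, strategy, focal_latlon,
                candidate_countries=countries, focal_country=focal_country,
            )
            row.update({
                "model": model_label,
                "cluster": cid,
                "n_pixels": int(len(cluster)),
                "focal_index": int(f),
                "focal_lat": focal_latlon[0],
                "focal_lon": focal_latlon[1],
            })
            rows.append(row)
    cols = ["model", "cluster", "n_pixels", "strategy", "focal_index", "focal_lat",
            "focal_lon", "donor_index", "donor_lat", "donor_lon", "distance_km", "load"]
    if countries is not None:
        cols += ["focal_country", "donor_country", "transboundary"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def summarize(plans: pd.DataFrame) -> dict:
    """Pooled summary across climate models, per strategy: vulnerable-area
    count, migration distance min/mean/SD/max, transboundary percentage and
    migration load min/mean/max."""
    if len(plans) == 0:
        raise ValueError("no migration plans to summarize")
    out = {}
    for strategy, g in plans.groupby("strategy"):
        d = g["distance_km"].to_numpy(float)
        load = g["load"].to_numpy(float)
        entry = {
            "n_areas": int(len(g)),
            "distance_km": {
                "min": float(d.min()), "mean": float(d.mean()),
                "sd": float(d.std()), "max": float(d.max()),
            },
            "load": {
                "min": float(load.min()), "mean": float(load.mean()),
                "max": float(load.max()),
            },
        }
        if "transboundary" in g.columns:
            entry["transboundary_pct"] = float(100.0 * g["transboundary"].mean())
        out[strategy] = entry
    return out
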