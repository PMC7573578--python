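"""Daily climate grids, monsoon-onset detection and the windowed agro-climate
metric catalog.

The growing season of rainfed Sahelian crops is anchored on the monsoon onset:
farmers sow after the first agronomically significant rainfall.  All seasonal
statistics are therefore computed inside windows of 30–180 days *after* the
detected onset rather than on calendar months.  The catalog pairs one onset
metric with 26 base statistics over five variable families (precipitation,
mean/max/min near-surface air temperature, downwelling shortwave radiation),
each evaluated on six windows, for 1 + 6 x 26 = 157 metrics per site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: window lengths (days after onset) of the metric catalog
WINDOWS = (30, 60, 90, 120, 150, 180)

ONSET_METRIC = "onset_day"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DailyClimateGrid:
    """Per-pixel daily series of the five weather variables for one period.

    Arrays are shaped ``(n_pixels, n_days)``; ``lat``/``lon`` give pixel
    centers in degrees.  Units: precip mm/day, temperatures degC, srad W/m2.
    """

    lat: np.ndarray
    lon: np.ndarray
    precip: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    srad: np.ndarray
    period: str = "current"
    model: str = "model0"
    scenario: str = ""

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        for name in ("precip", "tmean", "tmax", "tmin", "srad"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float)))

    @property
    def n_pixels(self) -> int:
        return self.lat.size

    @property
    def n_days(self) -> int:
        return self.precip.shape[1]

    def validate(self, min_days: int = 210) -> None:
        if self.n_pixels == 0:
            raise ValueError("degenerate grid: 0 pixels")
        shapes = {v.shape for v in (self.precip, self.tmean, self.tmax, self.tmin, self.srad)}
        if len(shapes) != 1 or self.precip.shape[0] != self.n_pixels:
            raise ValueError("climate variables must share shape (n_pixels, n_days)")
        if self.n_days < min_days:
            raise ValueError(
                f"series length {self.n_days} < {min_days}; cannot cover onset + 180-day window"
            )
        if np.any(self.precip < 0):
            raise ValueError("negative precipitation")
        if np.any(self.tmin > self.tmean) or np.any(self.tmean > self.tmax):
            raise ValueError("temperature ordering violated (tmin <= tmean <= tmax)")

    def pixel_index(self, lat: float, lon: float) -> int:
        """Index of the pixel whose center is nearest to (lat, lon)."""
        return int(np.argmin((self.lat - lat) ** 2 + (self.lon - lon) ** 2))


class ClimateMetricTable:
    """Sites x metric-catalog table.

    ``frame`` holds one row per site (indexed by site id) with columns
    ``lat``, ``lon`` followed by the metric catalog.
    """

    META_COLS = ("lat", "lon")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.META_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"metric table missing columns {missing}")
        self.frame = frame

    @property
    def metric_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.META_COLS]

    @property
    def metrics(self) -> pd.DataFrame:
        """The metric columns only (sites x catalog)."""
        return self.frame[self.metric_names]

    @property
    def lat(self) -> np.ndarray:
        return self.frame["lat"].to_numpy()

    @property
    def lon(self) -> np.ndarray:
        return self.frame["lon"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def subset_metrics(self, names: list[str]) -> "ClimateMetricTable":
        return ClimateMetricTable(self.frame[list(self.META_COLS) + list(names)])

    def at_sites(self, lat, lon, ids=None) -> "ClimateMetricTable":
        """Metric rows for arbitrary sites, taken from each site's containing
        (nearest-center) pixel — site climate is the pixel's climate, not an
        interpolation."""
        lat = np.asarray(lat, float)
        lon = np.asarray(lon, float)
        idx = [
            int(np.argmin((self.lat - la) ** 2 + (self.lon - lo) ** 2))
            for la, lo in zip(lat, lon)
        ]
        out = self.frame.iloc[idx].copy()
        out["lat"] = lat
        out["lon"] = lon
        out.index = ids if ids is not None else np.arange(len(idx))
        return ClimateMetricTable(out)


# ---------------------------------------------------------------------------
# monsoon onset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetRule:
    """Agronomic sowing-onset rule.

    Onset is the first day ``d`` (>= ``search_start``) such that rainfall
    accumulated over ``wet_spell_days`` days starting at ``d`` reaches
    ``wet_spell_mm``, and the following ``dry_check_days`` days contain no dry
    spell of ``dry_spell_days`` or more consecutive days below
    ``dry_threshold_mm``.
    """

    wet_spell_mm: float = 20.0
    wet_spell_days: int = 3
    dry_spell_days: int = 7
    dry_threshold_mm: float = 1.0
    dry_check_days: int = 20
    search_start: int = 0


def _max_dry_run(is_dry: np.ndarray) -> int:
    if is_dry.size == 0:
        return 0
    padded = np.concatenate(([0], is_dry.astype(int), [0]))
    edges = np.flatnonzero(np.diff(padded))
    if edges.size == 0:
        return 0
    return int(np.max(edges[1::2] - edges[::2]))


def detect_monsoon_onset(precip: np.ndarray, rule: OnsetRule = OnsetRule()) -> int | None:
    """First day satisfying the onset rule, or None if no day qualifies."""
    precip = np.asarray(precip, dtype=float)
    if precip.ndim != 1:
        raise ValueError("precip must be a 1-d daily series")
    if np.any(precip < 0):
        raise ValueError("negative precipitation")
    n = precip.size
    k = rule.wet_spell_days
    wet_sum = np.convolve(precip, np.ones(k), mode="valid")  # sum over [d, d+k)
    candidates = np.flatnonzero(wet_sum >= rule.wet_spell_mm)
    is_dry = precip < rule.dry_threshold_mm
    for d in candidates:
        if d < rule.search_start:
            continue
        lo = d + k
        hi = min(lo + rule.dry_check_days, n)
        if _max_dry_run(is_dry[lo:hi]) >= rule.dry_spell_days:
            continue
        return int(d)
    return None


def detect_onset_grid(grid: DailyClimateGrid, rule: OnsetRule = OnsetRule()) -> np.ndarray:
    """Per-pixel onset day; NaN where no day qualifies."""
    out = np.full(grid.n_pixels, np.nan)
    for i in range(grid.n_pixels):
        d = detect_monsoon_onset(grid.precip[i], rule)
        if d is not None:
            out[i] = d
    return out


# ---------------------------------------------------------------------------
# metric registry
# ---------------------------------------------------------------------------

def _sdii(x):  # simple daily intensity: mean rain on wet days
    wet = x > 1.0
    return float(x[wet].mean()) if wet.any() else 0.0


def default_registry(
    tmean_hot_c: float = 30.0,
    tmax_hot_c: float = 35.0,
    tmin_warm_c: float = 25.0,
    srad_low_wm2: float = 150.0,
    wet_day_mm: float = 1.0,
    heavy_day_mm: float = 20.0,
) -> dict[str, list[tuple[str, callable]]]:
    """The 26-base-metric registry: 10 precipitation statistics and 4 per
    temperature family and for shortwave radiation.  Swappable: any mapping
    ``family -> [(stat_name, fn)]`` with the same structure works."""
    dry = lambda x: x < wet_day_mm
    precip = [
        ("total", lambda x: float(x.sum())),
        ("mean", lambda x: float(x.mean())),
        ("max_daily", lambda x: float(x.max())),
        ("wet_days", lambda x: int((x > wet_day_mm).sum())),
        ("heavy_days", lambda x: int((x > heavy_day_mm).sum())),
        ("max_dry_spell", lambda x: _max_dry_run(dry(x))),
        ("max_wet_spell", lambda x: _max_dry_run(~dry(x))),
        ("sdii", _sdii),
        ("p95_daily", lambda x: float(np.percentile(x, 95))),
        ("dry_days", lambda x: int(dry(x).sum())),
    ]
    def temp_family(threshold):
        return [
            ("mean", lambda x: float(x.mean())),
            ("min", lambda x: float(x.min())),
            ("max", lambda x: float(x.max())),
            ("days_above", lambda x, t=threshold: int((x > t).sum())),
        ]
    srad = [
        ("mean", lambda x: float(x.mean())),
        ("min", lambda x: float(x.min())),
        ("max", lambda x: float(x.max())),
        ("low_days", lambda x: int((x < srad_low_wm2).sum())),
    ]
    return {
        "precip": precip,
        "tmean": temp_family(tmean_hot_c),
        "tmax": temp_family(tmax_hot_c),
        "tmin": temp_family(tmin_warm_c),
        "srad": srad,
    }


def catalog_names(registry=None, windows=WINDOWS) -> list[str]:
    """Full metric catalog name list: onset + {family}_{stat}_w{window}."""
    registry = registry if registry is not None else default_registry()
    names = [ONSET_METRIC]
    for w in windows:
        for family, stats in registry.items():
            for stat, _ in stats:
                names.append(f"{family}_{stat}_w{w}")
    return names


def compute_metrics(
    grid: DailyClimateGrid,
    onset: np.ndarray | None = None,
    registry=None,
    windows=WINDOWS,
    rule: OnsetRule = OnsetRule(),
    site_ids=None,
) -> ClimateMetricTable:
    """Compute the full metric catalog for every pixel of ``grid``.

    Windows are half-open ``[onset, onset + W)`` day-index ranges; the onset
    day itself is included.  Pixels with a missing onset are dropped with a
    warning; a window extending past the series end is an error naming the
    pixel.
    """
    grid.validate()
    registry = registry if registry is not None else default_registry()
    if onset is None:
        onset = detect_onset_grid(grid, rule)
    onset = np.asarray(onset, dtype=float)

    keep = ~np.isnan(onset)
    if not keep.all():
        dropped = int((~keep).sum())
        logger.warning("dropping %d pixel(s) with missing monsoon onset", dropped)
        warnings.warn(f"dropping {dropped} pixel(s) with missing monsoon onset")

    families = {"precip": grid.precip, "tmean": grid.tmean, "tmax": grid.tmax,
                "tmin": grid.tmin, "srad": grid.srad}
    names = catalog_names(registry, windows)
    rows = []
    kept_idx = np.flatnonzero(keep)
    for i in kept_idx:
        d0 = int(onset[i])
        if d0 + max(windows) > grid.n_days:
            raise ValueError(
                f"pixel {i} (lat={grid.lat[i]:.3f}, lon={grid.lon[i]:.3f}): "
                f"window [{d0}, {d0 + max(windows)}) extends past series end {grid.n_days}"
            )
        row = [float(d0)]
        for w in windows:
            for family, stats in registry.items():
                seg = families[family][i, d0:d0 + w]
                for _, fn in stats:
                    row.append(fn(seg))
        rows.append(row)

    ids = np.asarray(site_ids)[kept_idx] if site_ids is not None else kept_idx
    frame = pd.DataFrame(rows, columns=names, index=ids)
    frame.insert(0, "lat", grid.lat[kept_idx])
    frame.insert(1, "lon", grid.lon[kept_idx])
    if not np.isfinite(frame[names].to_numpy()).all():
        raise ValueError("non-finite metric values computed")
    return ClimateMetricTable(frame)


# ---------------------------------------------------------------------------
# decorrelation filter
# ---------------------------------------------------------------------------

def select_uncorrelated(
    metrics: ClimateMetricTable | pd.DataFrame,
    r_max: float = 0.7,
    order: list[str] | None = None,
) -> list[str]:
    """Greedy forward decorrelation at Pearson ``|r| <= r_max``.

    Metrics are visited in ``order`` (importance rank when a fitted turnover
    model supplies one, catalog order otherwise); a metric is kept iff its
    absolute Pearson correlation with every already-kept metric is at most
    ``r_max``.  Zero-variance metrics are excluded with a warning.
    """
    df = metrics.metrics if isinstance(metrics, ClimateMetricTable) else metrics
    if len(df) < 2:
        raise ValueError("need at least 2 sites to estimate correlations")
    cols = list(order) if order is not None else list(df.columns)
    X = df[cols].to_numpy(float)
    sd = X.std(axis=0)
    kept: list[str] = []
    kept_z: list[np.ndarray] = []
    n = X.shape[0]
    for j, name in enumerate(cols):
        if sd[j] == 0:
            warnings.warn(f"metric {name!r} has zero variance; excluded")
            continue
        z = (X[:, j] - X[:, j].mean()) / sd[j]
        if all(abs(float(z @ zk) / n) <= r_max for zk in kept_z):
            kept.append(name)
            kept_z.append(z)
    return kept
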