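"""Seeded synthetic inputs with the statistical structure the analysis
assumes: a West-Africa-like half-degree grid with a latitudinal monsoon
gradient, landraces scattered over it, allele-frequency clines driven by a
designated climate metric plus neutral background SNPs, bimodal flowering
times, and yield traits declining with climate mismatch.

Every generator is a pure function of (scenario, seed): identical inputs
give bit-identical outputs.  The climate generator draws one weather-noise
realisation and renders both periods from it, so a zero perturbation
(``onset_shift_days=0, precip_scale=1, warming_c=0``) makes the future grid
identical to the current one — the null case against which the offset
identity is tested.

Simplifications (documented): frequency noise is truncated Gaussian rather
than Beta-binomial pool-seq read noise, and no linkage disequilibrium is
simulated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import (
    ClimateMetricTable,
    DailyClimateGrid,
    ONSET_METRIC,
)

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "generate_climate",
    "generate_landraces",
    "generate_allele_freqs",
    "generate_phenotypes",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    Defaults emulate the Sahelian pearl-millet setting: a 0.5-degree grid
    across the monsoon gradient, ~10² georeferenced landraces from a handful
    of countries, a few dozen climate-driven SNPs against a neutral
    background, and a mid-century warming/drying perturbation.
    """

    lat_range: tuple[float, float] = (10.0, 16.0)
    lon_range: tuple[float, float] = (-16.0, 2.0)
    resolution: float = 0.5
    n_landraces: int = 150
    n_adaptive_snps: int = 20
    n_neutral_snps: int = 180
    cline_steepness: float = 2.0
    noise_sd: float = 0.05
    onset_shift_days: int = 10
    precip_scale: float = 0.9
    warming_c: float = 2.0
    n_countries: int = 5
    n_days: int = 400  # headroom for onset + 180-day window under delayed monsoons
    seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.lat_range[1] <= self.lat_range[0] or self.lon_range[1] <= self.lon_range[0]:
            raise ValueError("lat/lon ranges must be non-degenerate")
        if self.n_adaptive_snps + self.n_neutral_snps < 1:
            raise ValueError("need at least one SNP")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def grid_centers(self) -> tuple[np.ndarray, np.ndarray]:
        lats = np.arange(self.lat_range[0] + self.resolution / 2, self.lat_range[1],
                         self.resolution)
        lons = np.arange(self.lon_range[0] + self.resolution / 2, self.lon_range[1],
                         self.resolution)
        glon, glat = np.meshgrid(lons, lats)
        return glat.ravel(), glon.ravel()

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible substream per generator stage."""
        tag = zlib.crc32(stream.encode()) % 2**31
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    adaptive_snps: list[str]
    driver_metric: str
    thresholds: dict[str, float]
    causal_flowering_snps: list[str] = field(default_factory=list)
    flowering_effects: dict[str, float] = field(default_factory=dict)
    common_garden: tuple[float, float] | None = None
    climate_mismatch: pd.Series | None = None


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def _season_envelope(days: np.ndarray, start: np.ndarray, length: float) -> np.ndarray:
    """Smooth rainy-season intensity envelope in [0, 1], per pixel x day."""
    x = (days[None, :] - start[:, None]) / length
    env = np.where((x >= 0) & (x <= 1), np.sin(np.pi * np.clip(x, 0, 1)) ** 2, 0.0)
    return env


def generate_climate(
    scenario: SyntheticScenario,
) -> tuple[DailyClimateGrid, DailyClimateGrid]:
    """Current and future daily grids sharing one weather-noise realisation.

    The rainy season starts later at higher latitude (the monsoon arrives
    from the south); the future period delays the season start by
    ``onset_shift_days``, scales rainfall by ``precip_scale`` and warms all
    temperatures by ``warming_c``.
    """
    lat, lon = scenario.grid_centers()
    if lat.size == 0:
        raise ValueError("degenerate grid: 0 pixels")
    n_pix, n_days = lat.size, scenario.n_days
    days = np.arange(n_days, dtype=float)
    rng = scenario.rng("climate")

    # shared weather noise between the two periods
    u_wet = rng.random((n_pix, n_days))
    rain_amount = rng.gamma(shape=2.0, scale=1.0, size=(n_pix, n_days))
    t_noise = rng.normal(0.0, 0.4, size=(n_pix, n_days))
    spread = np.abs(rng.normal(0.0, 0.5, size=(n_pix, n_days)))
    s_noise = rng.normal(0.0, 12.0, size=(n_pix, n_days))

    # season start climbs with latitude: ~6 days per degree
    base_start = 100.0 + 6.0 * (lat - scenario.lat_range[0])
    season_len = 140.0

    def render(start, precip_scale, warming):
        env = _season_envelope(days, start, season_len)
        wet = u_wet < (0.06 + 0.74 * env)
        precip = precip_scale * wet * rain_amount * (1.0 + 11.0 * env)
        tmean = (34.0 - 0.3 * (lat[:, None] - 10.0)) - 5.0 * env + t_noise + warming
        tmax = tmean + 5.0 + spread
        tmin = tmean - 7.0 - spread
        srad = np.clip(265.0 - 90.0 * env + s_noise, 50.0, None)
        return precip, tmean, tmax, tmin, srad

    cur = render(base_start, 1.0, 0.0)
    fut = render(base_start + scenario.onset_shift_days, scenario.precip_scale,
                 scenario.warming_c)

    current = DailyClimateGrid(lat, lon, *cur, period="current")
    future = DailyClimateGrid(lat, lon, *fut, period="future")
    current.validate()
    future.validate()
    return current, future


# ---------------------------------------------------------------------------
# landraces
# ---------------------------------------------------------------------------

def generate_landraces(scenario: SyntheticScenario, grid: DailyClimateGrid) -> pd.DataFrame:
    """Landrace table: id, lat, lon, country (longitudinal bands), pixel index.

    Points are uniform over the grid's bounding box (hence inside the pixel
    hull); countries are a deterministic partition of longitude into
    ``n_countries`` equal bands.
    """
    if grid.n_pixels == 0:
        raise ValueError("grid is empty")
    if scenario.n_landraces < 2:
        raise ValueError("need at least 2 landraces")
    rng = scenario.rng("landraces")
    la0, la1 = grid.lat.min(), grid.lat.max()
    lo0, lo1 = grid.lon.min(), grid.lon.max()
    lat = rng.uniform(la0, la1, scenario.n_landraces)
    lon = rng.uniform(lo0, lo1, scenario.n_landraces)
    band = np.floor((lon - lo0) / (lo1 - lo0 + 1e-12) * scenario.n_countries)
    band = np.clip(band, 0, scenario.n_countries - 1).astype(int)
    pixel = [grid.pixel_index(la, lo) for la, lo in zip(lat, lon)]
    return pd.DataFrame(
        {
            "id": [f"LR{i:04d}" for i in range(scenario.n_landraces)],
            "lat": lat,
            "lon": lon,
            "country": [f"C{b}" for b in band],
            "pixel": pixel,
        }
    ).set_index("id")


def pixel_countries(scenario: SyntheticScenario, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Country label of arbitrary points under the same longitudinal bands."""
    lo0, lo1 = scenario.lon_range
    band = np.floor((np.asarray(lon) - lo0) / (lo1 - lo0 + 1e-12) * scenario.n_countries)
    band = np.clip(band, 0, scenario.n_countries - 1).astype(int)
    return np.array([f"C{b}" for b in band])


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def generate_allele_freqs(
    scenario: SyntheticScenario,
    landraces: pd.DataFrame,
    metrics: ClimateMetricTable,
    driver_metric: str = ONSET_METRIC,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Clinal adaptive SNPs plus neutral background SNPs.

    Adaptive SNP j has expected frequency ``logistic(steepness * (z - c_j))``
    in the standardised driver metric z at the landrace's site; neutral SNP
    frequencies are site-independent Beta draws.  Truncated-Gaussian noise of
    SD ``noise_sd`` is added and frequencies clipped to [0, 1].
    """
    if driver_metric not in metrics.frame.columns:
        raise ValueError(f"driver metric {driver_metric!r} not in metric table")
    missing = [i for i in landraces.index if i not in metrics.frame.index]
    if missing:
        raise ValueError(f"metric table missing landrace sites: {missing[:5]}")
    rng = scenario.rng("freqs")
    z = metrics.frame.loc[landraces.index, driver_metric].to_numpy(float)
    z = (z - z.mean()) / (z.std() + 1e-12)

    n = len(landraces)
    cols, data = [], []
    thresholds = {}
    for j in range(scenario.n_adaptive_snps):
        c = rng.normal(0.0, 0.5)
        name = f"adaptive_{j:03d}"
        mu = 1.0 / (1.0 + np.exp(-scenario.cline_steepness * (z - c)))
        data.append(mu)
        cols.append(name)
        thresholds[name] = float(c)
    for j in range(scenario.n_neutral_snps):
        mean = rng.uniform(0.15, 0.85)
        conc = 30.0
        data.append(rng.beta(mean * conc, (1 - mean) * conc, size=n))
        cols.append(f"neutral_{j:03d}")

    F = np.column_stack(data) if data else np.empty((n, 0))
    if scenario.noise_sd > 0:
        F = F + rng.normal(0.0, scenario.noise_sd, size=F.shape)
    F = np.clip(F, 0.0, 1.0)
    freqs = pd.DataFrame(F, index=landraces.index, columns=cols)
    truth = GroundTruth(
        adaptive_snps=[c for c in cols if c.startswith("adaptive_")],
        driver_metric=driver_metric,
        thresholds=thresholds,
    )
    return freqs, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def generate_phenotypes(
    scenario: SyntheticScenario,
    landraces: pd.DataFrame,
    freqs: pd.DataFrame,
    truth: GroundTruth,
    metrics: ClimateMetricTable | None = None,
    grid_metrics: ClimateMetricTable | None = None,
    flowering_baseline: float = 60.0,
    flowering_effect: float = 50.0,
    flowering_noise_sd: float = 4.0,
    n_causal: int = 1,
    common_garden: tuple[float, float] | None = None,
    yield_noise_frac: float = 0.15,
) -> pd.DataFrame:
    """Flowering time and yield traits.

    Flowering time is ``baseline + sum(effect * frequency)`` over a causal
    subset of adaptive SNPs plus Gaussian noise; with a steep cline the
    causal frequencies sit near 0 or 1, which makes the marginal flowering
    distribution bimodal (early ~60 d and late ~110 d modes).  Yield traits
    (100-seed weight g, main-spike seed weight g, seeds per plant) decline
    linearly with the climate mismatch between each landrace's origin and a
    common-garden site (grid centre by default).  ``metrics`` is the
    landrace-site metric table (indexed by landrace id); ``grid_metrics``,
    when given, is the pixel-level table used to resolve the garden's
    climate (so the ground truth references the same pixel the downstream
    vulnerability analysis will).
    """
    if n_causal < 1:
        raise ValueError("flowering requires a non-empty causal SNP subset")
    if len(truth.adaptive_snps) < n_causal:
        raise ValueError("not enough adaptive SNPs for the causal subset")
    rng = scenario.rng("phenotypes")
    causal = truth.adaptive_snps[:n_causal]
    eff = flowering_effect / n_causal
    flowering = flowering_baseline + sum(eff * freqs[c].to_numpy(float) for c in causal)
    if flowering_noise_sd > 0:
        flowering = flowering + rng.normal(0.0, flowering_noise_sd, size=len(landraces))

    out = pd.DataFrame({"flowering_days": flowering}, index=landraces.index)
    truth.causal_flowering_snps = list(causal)
    truth.flowering_effects = {c: eff for c in causal}

    if metrics is not None:
        if common_garden is None:
            common_garden = (
                float(np.mean(scenario.lat_range)), float(np.mean(scenario.lon_range))
            )
        lookup = grid_metrics if grid_metrics is not None else metrics
        garden = lookup.at_sites([common_garden[0]], [common_garden[1]]).frame.iloc[0]
        z_site = float(garden[truth.driver_metric])
        z = metrics.frame.loc[landraces.index, truth.driver_metric].to_numpy(float)
        sd = z.std() + 1e-12
        mismatch = np.abs(z - z_site) / sd
        baselines = {"seed_weight_100": 1.0, "spike_seed_weight": 30.0,
                     "seeds_per_plant": 3000.0}
        for trait, base in baselines.items():
            slope = 0.25 * base  # yield loss per SD of climate mismatch
            noise = rng.normal(0.0, yield_noise_frac * base, size=len(landraces))
            out[trait] = base - slope * mismatch + noise
        truth.common_garden = common_garden
        truth.climate_mismatch = pd.Series(mismatch, index=landraces.index)
    return out
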