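"""End-to-end pipeline driver: climate metrics -> gradient-forest fits (one
per climate model) -> vulnerability map -> migration plans -> summaries."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as cm
from . import gf, io, migration, synthetic, vulnerability

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single source of pipeline constants (CLI flags override these)."""

    outdir: str = "pipeline_out"
    seed: int = 0
    maf_gf: float = 0.10
    maf_gwas: float = 0.05
    n_trees: int = 500
    k_latent: int | None = None
    fdr_alpha: float = 0.05
    vuln_quantile: float = 0.90
    min_pts: int = 4
    eps_km: float = 300.0
    merge_km: float = 1200.0
    strategy_quantiles: tuple[float, float] = (0.01, 0.05)
    decorrelate_r: float = 0.7
    use_decorrelated: bool = False
    onset_rule: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)  # synthetic-run parameters
    paths: dict = field(default_factory=dict)     # file-input runs

    def validate(self) -> None:
        checks = [
            0 < self.maf_gf < 0.5, 0 < self.maf_gwas < 0.5, self.n_trees >= 1,
            0 < self.fdr_alpha < 1, 0 < self.vuln_quantile < 1, self.min_pts >= 1,
            self.eps_km > 0, 0 < self.decorrelate_r <= 1,
            all(0 < q < 1 for q in self.strategy_quantiles),
        ]
        if not all(checks):
            raise ValueError("pipeline config contains out-of-range thresholds")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "strategy_quantiles" in d:
            d["strategy_quantiles"] = tuple(d["strategy_quantiles"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Hash of the analysis constants (file locations excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k not in ("outdir", "paths")}
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the synthetic end-to-end pipeline and write its artifacts.

    Returns the summary dictionary (also written as JSON).  Deterministic:
    the same config (including seed) produces byte-identical summary files.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    def stage(name):
        logger.info("stage: %s", name)
        stage_times[name] = time.time()
        return name

    try:
        stage("simulate")
        scenario = synthetic.SyntheticScenario(**{"seed": config.seed, **config.scenario})
        current, future = synthetic.generate_climate(scenario)
        landraces = synthetic.generate_landraces(scenario, current)

        stage("metrics")
        rule = cm.OnsetRule(**config.onset_rule)
        cur_metrics = cm.compute_metrics(current, rule=rule)
        fut_metrics = cm.compute_metrics(future, rule=rule)
        # align future pixels to current (onset may be missing differently)
        common = cur_metrics.frame.index.intersection(fut_metrics.frame.index)
        cur_metrics = cm.ClimateMetricTable(cur_metrics.frame.loc[common])
        fut_metrics = cm.ClimateMetricTable(fut_metrics.frame.loc[common])
        lr_metrics = cur_metrics.at_sites(landraces["lat"], landraces["lon"],
                                          ids=landraces.index)
        summary["n_pixels"] = int(len(cur_metrics))
        summary["n_metrics"] = len(cur_metrics.metric_names)

        stage("freqs")
        freqs, truth = synthetic.generate_allele_freqs(scenario, landraces, lr_metrics)
        phenos = synthetic.generate_phenotypes(scenario, landraces, freqs, truth,
                                               metrics=lr_metrics,
                                               grid_metrics=cur_metrics)

        stage("gf")
        kept = gf.filter_maf(freqs, config.maf_gf)
        summary["n_snps_input"] = int(freqs.shape[1])
        summary["n_snps_maf"] = int(kept.shape[1])
        predictor_names = cm.select_uncorrelated(lr_metrics, config.decorrelate_r) \
            if config.use_decorrelated else lr_metrics.metric_names
        model = gf.fit(kept, lr_metrics.subset_metrics(predictor_names),
                       n_trees=config.n_trees, seed=config.seed)
        frac, n_pos, n_all = gf.fraction_predicted(model)
        summary["fraction_snps_predicted"] = frac
        io.write_model(model, outdir / "model.gf.json")

        stage("vulnerability")
        hull = vulnerability.cultivation_hull(landraces["lat"], landraces["lon"])
        cur_sub = cur_metrics.subset_metrics(predictor_names)
        fut_sub = fut_metrics.subset_metrics(predictor_names)
        vmap = vulnerability.map_offsets({current.model: (model, cur_sub, fut_sub)},
                                         hull=hull)
        vmap.to_csv(outdir / "vulnerability.csv", index=False)
        summary["mean_offset"] = float(vmap["mean"].mean())
        summary["max_offset"] = float(vmap["mean"].max())

        stage("migration")
        countries = synthetic.pixel_countries(
            scenario, vmap["lat"].to_numpy(), vmap["lon"].to_numpy())
        pix_key = [f"{la:.4f}|{lo:.4f}" for la, lo in zip(cur_sub.lat, cur_sub.lon)]
        sel = pd.Series(np.arange(len(pix_key)), index=pix_key)
        order = sel[[f"{la:.4f}|{lo:.4f}" for la, lo in
                     zip(vmap["lat"], vmap["lon"])]].to_numpy()
        cur_in_hull = cm.ClimateMetricTable(cur_sub.frame.iloc[order])
        fut_in_hull = cm.ClimateMetricTable(fut_sub.frame.iloc[order])
        if vmap["mean"].max() <= 0:
            plans = pd.DataFrame()
            summary["n_vulnerable_areas"] = 0
        else:
            plans = migration.plan_migrations(
                model, vmap, f"offset_{current.model}", cur_in_hull, fut_in_hull,
                countries=countries, model_label=current.model,
                q=config.vuln_quantile, min_pts=config.min_pts,
                eps_km=config.eps_km, merge_km=config.merge_km)
            io.write_plans(plans, outdir / "migration_plans.csv")
            io.write_json(io.plans_to_geojson(plans), outdir / "migration_plans.geojson")
            summary["n_vulnerable_areas"] = int(plans["cluster"].nunique()) if len(plans) else 0
            if len(plans):
                summary["migration"] = migration.summarize(plans)
    except Exception as exc:
        failed = list(stage_times)[-1] if stage_times else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    io.write_landraces(landraces, outdir / "landraces.csv")
    io.write_phenotypes(phenos, outdir / "phenotypes.csv")
    io.write_allele_freqs(freqs, outdir / "allele_freqs.csv")
    io.write_metrics(lr_metrics, outdir / "landrace_metrics.csv",
                     outdir / "metric_manifest.json")
    io.write_json(summary, outdir / "summary.json")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": list(stage_times),
    }
    io.write_json(manifest, outdir / "manifest.json")
    return summary
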