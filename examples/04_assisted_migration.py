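"""Plan assisted migration: cluster the most vulnerable pixels, then find
donor varieties under optimal / near-optimal / sub-optimal strategies."""

import json

import climoffset as co
from climoffset import migration as mg
from climoffset import vulnerability as vu
from climoffset.climate import ClimateMetricTable

scenario = co.SyntheticScenario(seed=7)
current, future = co.generate_climate(scenario)
cur_m = co.compute_metrics(current)
fut_m = co.compute_metrics(future)
common = cur_m.frame.index.intersection(fut_m.frame.index)
cur_m = ClimateMetricTable(cur_m.frame.loc[common])
fut_m = ClimateMetricTable(fut_m.frame.loc[common])
landraces = co.generate_landraces(scenario, current)
lrm = cur_m.at_sites(landraces["lat"], landraces["lon"], ids=landraces.index)
freqs, _ = co.generate_allele_freqs(scenario, landraces, lrm)

predictors = co.select_uncorrelated(lrm, 0.7)
model = co.fit(co.filter_maf(freqs, 0.10), lrm.subset_metrics(predictors),
               n_trees=100, seed=7)

hull = vu.cultivation_hull(landraces["lat"], landraces["lon"])
cur_sub = cur_m.subset_metrics(predictors)
fut_sub = fut_m.subset_metrics(predictors)
vmap = vu.map_offsets({"m0": (model, cur_sub, fut_sub)}, hull=hull)

keys = {f"{la:.4f}|{lo:.4f}": i for i, (la, lo) in enumerate(zip(cur_sub.lat, cur_sub.lon))}
sel = [keys[f"{la:.4f}|{lo:.4f}"] for la, lo in zip(vmap["lat"], vmap["lon"])]
countries = co.synthetic.pixel_countries(scenario, vmap["lat"].to_numpy(),
                                         vmap["lon"].to_numpy())
plans = mg.plan_migrations(
    model, vmap, "offset_m0",
    ClimateMetricTable(cur_sub.frame.iloc[sel]),
    ClimateMetricTable(fut_sub.frame.iloc[sel]),
    countries=countries, model_label="m0")

print(f"vulnerable areas (top-10% pixels, DBSCAN, >=4 pixels): "
      f"{plans['cluster'].nunique()}")
print(json.dumps(mg.summarize(plans), indent=1))
# Relaxing the donor criterion (optimal -> near -> sub-optimal) shortens the
# migration distance but raises the migration load: the residual maladaptation
# of the migrated variety under the focal site's future climate.
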