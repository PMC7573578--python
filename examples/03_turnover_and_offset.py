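"""Fit the gradient-forest turnover model and map genomic vulnerability
(the Euclidean offset between transformed current and future climates)."""

import climoffset as co
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
freqs, truth = co.generate_allele_freqs(scenario, landraces, lrm)

kept = co.filter_maf(freqs, 0.10)                      # folded MAF > 10%
predictors = co.select_uncorrelated(lrm, 0.7)
model = co.fit(kept, lrm.subset_metrics(predictors), n_trees=100, seed=7)

frac, n_pos, n_all = co.fraction_predicted(model)
top = model.importance.sort_values(ascending=False).head(3)
print(f"{n_pos}/{n_all} SNPs predictable (R2 > 0), fraction {frac:.2f}")
print("top predictors by aggregate turnover importance:")
print(top.round(4).to_string())
print(f"planted driver was: {truth.driver_metric}")

hull = vu.cultivation_hull(landraces["lat"], landraces["lon"])
vmap = vu.map_offsets(
    {"m0": (model, cur_m.subset_metrics(predictors), fut_m.subset_metrics(predictors))},
    hull=hull)
print(f"vulnerability map: {len(vmap)} pixels inside the cultivation hull, "
      f"offsets {vmap['mean'].min():.4f}-{vmap['mean'].max():.4f} "
      "(larger = more allele-frequency change needed to track climate)")
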