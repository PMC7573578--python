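"""Generate a seeded synthetic study: climate grids, landraces, allele
frequencies and phenotypes with known planted structure."""

import climoffset as co

scenario = co.SyntheticScenario(seed=42)
current, future = co.generate_climate(scenario)
landraces = co.generate_landraces(scenario, current)
metrics = co.compute_metrics(current)
lr_metrics = metrics.at_sites(landraces["lat"], landraces["lon"], ids=landraces.index)
freqs, truth = co.generate_allele_freqs(scenario, landraces, lr_metrics)
phenos = co.generate_phenotypes(scenario, landraces, freqs, truth,
                                metrics=lr_metrics, grid_metrics=metrics)

print(f"grid: {current.n_pixels} half-degree pixels x {current.n_days} days")
print(f"landraces: {len(landraces)} across {landraces['country'].nunique()} countries")
print(f"allele frequencies: {freqs.shape[0]} landraces x {freqs.shape[1]} SNPs "
      f"({len(truth.adaptive_snps)} adaptive, driver = {truth.driver_metric})")
print(f"flowering time: {phenos['flowering_days'].min():.0f}-"
      f"{phenos['flowering_days'].max():.0f} days (bimodal early/late)")
# The adaptive SNPs follow logistic clines in the driver climate metric; the
# neutral SNPs are exchangeable background, so downstream models should find
# the driver and rank adaptive SNPs as more predictable.
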