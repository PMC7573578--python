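# Methods

This note records the models implemented in `climoffset`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
tests do and do not demonstrate.

## Monsoon onset and the metric catalog

Onset is defined agronomically: the first day `d` with
`sum(precip[d : d+3]) >= 20 mm` and no dry spell of ≥ 7 consecutive days
below 1 mm/day within the 20 days following the wet spell
(`[d+3, d+23)`).  All five constants are fields of `OnsetRule`.  This is a
standard Sahelian sowing-onset rule; the literature contains several
variants, which is why the rule is configurable rather than hard-coded.  An
all-dry series yields a missing onset (a sentinel, not an exception);
negative precipitation is an error.

The catalog is 1 onset metric plus 26 base statistics × 6 windows
(30, 60, 90, 120, 150, 180 days after onset) = 157 columns.  The registry:
precipitation gets 10 statistics (total, mean, max daily, wet days > 1 mm,
heavy days > 20 mm, max dry spell, max wet spell, simple daily intensity,
95th-percentile daily, dry days); each temperature family and shortwave
radiation get 4 (mean, min, max, and an event count — days with
tmean > 30 °C, tmax > 35 °C, tmin > 25 °C, srad < 150 W/m²).  Thresholds
are conventional agroclimate values and are registry parameters.  Windows
are half-open day-index ranges `[onset, onset+W)`; day indexing is 0-based;
the onset day belongs to its windows.  Site (landrace) metrics are taken
from the containing pixel, never interpolated.

Decorrelation is a greedy forward pass in a fixed metric order (catalog
order, or importance order when a fitted model supplies one): keep a metric
iff its absolute Pearson correlation with every kept metric is ≤ 0.7.
Zero-variance metrics are excluded with a warning because their correlation
is undefined.

## Gradient forest

Per SNP, a `RandomForestRegressor` (500 trees by default, `max_features`
p/3 rounded, bootstrap, unlimited depth) regresses allele frequency on the
climate predictors.  Out-of-bag R² below 0 is clamped to 0 and the SNP is
excluded from turnover aggregation — only SNPs with genuine out-of-sample
predictive power shape the climate transformation.

Turnover construction: each split's node-weighted impurity reduction is
assigned to the bin (201 per predictor, over the training range) containing
its threshold.  A SNP's binned gains are scaled by `R²_snp / total_gain` so
its mass across predictors sums to its R².  Aggregated bins are divided by
a smoothed histogram of the observed predictor values (the density of split
opportunities), cumulated, and rescaled so that `F_p(max)` equals the
predictor's aggregate importance (the R²-partitioned mean over predictive
SNPs).  `F_p` is a right-continuous non-decreasing step function with
`F_p(min) = 0`; evaluation clamps inputs to the training range, so
extrapolated climates saturate rather than invent turnover.  Constant
predictors are excluded from the forests (they can never be split on) and
re-enter the model with identically-zero turnover, which makes every other
turnover function exactly invariant to their presence.

Genomic offset between climates x and x′ is the Euclidean norm of
`F(x′) − F(x)` over all predictors — a true metric on transformed space.
Offsets can be computed on the full catalog or the decorrelated subset;
both are supported because collinear predictors dilute importance across
near-duplicates without changing the zero-offset identity.

## Vulnerability maps and ensembles

Offsets are mapped only for pixels whose centers fall inside the convex
hull of the landrace coordinates (the cultivation area).  Each climate
model gets its own fitted turnover model and its own offset surface;
ensemble summaries are per-pixel mean, **population** SD (the model
ensemble is fixed, not sampled — recorded in the output metadata), CV, and
a stipple flag for CV < 0.5 (mean > 2 SD), marking where the ensemble
agrees.

The common-garden validation computes, per landrace, the offset between the
climate at its origin and at a single trial site, then Pearson-correlates
it with yield traits (100-seed weight, main-spike seed weight, seeds per
plant).  Landraces outside the training metric range are transformed with
clamping and a warning; zero-variance traits are an error.

## Migration planning

Per climate model: pixels with offset at or above the 0.90 quantile are
clustered with DBSCAN on great-circle distance (haversine, sphere radius
6371.0088 km).  Defaults: `eps_km = 300` (about six half-degree pixels),
`min_pts = 4`; clusters with fewer than 4 pixels are discarded.  Clusters
whose focal (most vulnerable) pixels lie closer than 1200 km are merged
iteratively, closest pair first — a deterministic operator that keeps
retained areas well separated; the constant is configurable because the
separation rule admits more than one reading.  Focal-pixel ties break by
(lat, lon) lexicographic order.

Donor search: candidates are *all* cultivation pixels, the focal pixel
included, so self-donation is possible and meaningful (its load is the
pixel's own offset).  ED quantile pools are by rank, `ceil(n·q)` pixels
with a minimum of one; optimal ties break by geographic distance then
(lat, lon).  Because the near/sub-optimal pools nest and contain the
optimum, distance(sub) ≤ distance(near) ≤ distance(optimal) and
load(optimal) ≤ load(near/sub) hold structurally, and the tests assert them
on every run.  Summaries pool plans across climate models per strategy:
area counts, distance min/mean/SD/max, transboundary percentage, load
min/mean/max.

## Flowering-time association

The latent-factor model is the deterministic ridge/low-rank variant: the
factors are the top-K principal-component scores of the centred frequency
matrix, and each SNP's frequency is regressed on [1, phenotype, factors] in
one shared least-squares solve; the phenotype coefficient's t-statistic is
the test.  With K = 0 this reduces exactly to per-SNP simple regression.
Squared z-scores are divided by the genomic-inflation factor
(median χ² / 0.4549) before two-sided normal p-values; a Q–Q-style
comparison is available through the returned p-values.  K defaults to the
screeplot elbow (largest successive eigenvalue drop, capped), with a
low-structure warning when the top eigenvalue is < 1.5× the median; K is a
plain argument, so a user-chosen K (e.g. 5) is respected.  Selection is
Benjamini–Hochberg step-up at FDR 5% — deterministic and conservative
relative to π₀-estimating q-value methods, which is acceptable because the
selection is threshold-based.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
with every draw a pure function of (scenario, seed):

- **Climate**: a 0.5° grid over 10–16°N, 16°W–2°E; daily rainfall is a
  wet-day Bernoulli × Gamma process under a sin² seasonal envelope whose
  start climbs ~6 days per degree of latitude (the monsoon arrives from the
  south); temperatures and radiation carry opposite-phase seasonal cycles.
  Series are 400 days long so a delayed onset still leaves room for the
  180-day window.  The future period re-renders the *same* weather noise
  with the envelope delayed by `onset_shift_days` (default 10), rainfall
  scaled by `precip_scale` (default 0.9) and temperatures offset by
  `warming_c` (default +2 °C, a mid-century high-emissions magnitude).
  `warming_c` is an explicit scenario field.  Because noise is shared, a
  zero perturbation makes future and current bit-identical, which forces
  every downstream offset to zero — the null case the tests exploit.
- **Landraces**: 150 points uniform over the grid, countries as equal
  longitudinal bands (5 by default) — countries only feed the transboundary
  flag, so bands give controllable rates.
- **Allele frequencies**: 20 adaptive SNPs with expected frequency
  `logistic(2·(z − c_j))` in the standardised monsoon-onset metric z
  (thresholds c_j ~ N(0, 0.5²)), 180 neutral SNPs as site-independent Beta
  draws, truncated-Gaussian noise (SD 0.05) clipped to [0, 1].  The cline
  steepness of 2 makes causal frequencies near-saturated at the range ends,
  which is what produces the bimodal flowering distribution below.
- **Phenotypes**: flowering = 60 + 50·(causal frequency) + N(0, 4²) days —
  early (~60 d) and late (~110 d) modes; yield traits decline by 25% of
  their baseline per SD of climate mismatch between origin and a central
  common-garden pixel, with 15% baseline noise.  The ground-truth mismatch
  references the same grid pixel the downstream vulnerability analysis
  resolves for the garden.

Not emulated: pool-seq read sampling (noise is Gaussian on frequencies, not
Beta-binomial), linkage disequilibrium, isolation-by-distance beyond the
country bands, multiple interacting climate drivers per SNP, and climate
model structural diversity (an "ensemble" is perturbation variants).
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted signals under the assumed generative model — not
performance on real pool-seq data.

## Problem sizes and numerical choices

The default fitted configuration (500 trees/SNP) is used for real analyses;
the test suite and the acceptance script fit 40–100 trees per SNP on the
spec-sized synthetic studies (150 landraces, 200 SNPs, 20-seed replicates),
the package's own desk-scale choice — recovery statistics are insensitive
to tree count well below the default.  Stochastic recovery checks require
≥ 18 of 20 seeds.  Forest determinism comes from per-SNP seeds spawned from
one `SeedSequence`; generator substreams are keyed by CRC32 of the stage
name, so stages are independent and reproducible.  Degenerate inputs are
handled explicitly: constant SNPs get R² = 0, constant predictors zero
importance, zero-variance metrics and traits raise or warn as documented,
and quantile/argmin ties break lexicographically everywhere a choice is
needed.

## Known limitations

- The onset rule and the 26-metric registry are field-standard defaults,
  not a canonical set; both are configurable registries by design.
- The turnover density normalisation uses a smoothed histogram rather than
  the whitened kernel estimate of the original gradient-forest software;
  on the synthetic studies the resulting curves are indistinguishable in
  rank structure, but absolute cumulative-importance values should not be
  compared across implementations.
- The ridge-style LFMM is deterministic and fast but does not marginalise
  over factor uncertainty; with few landraces and strong structure its
  calibration relies on the genomic-control step.
- DBSCAN border-pixel assignment depends on pixel order; the fixed (lat,
  lon) pixel ordering makes it deterministic here.
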