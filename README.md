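# fishinvasion

Statistical-ecology pipeline for analysing large-scale freshwater fish
invasion from community survey data: invasion metrics, driver engineering,
boosted-regression-tree modelling with spatial-autocorrelation correction,
and variance decomposition across driver groups — with a synthetic-data
module so the whole chain is testable end to end without restricted survey
data.

It is written for ecologists and biostatisticians who work with site ×
species fish survey tables (ordinal Moyle abundance classes), per-site
environmental covariates, and river-network barrier inventories.

## What it computes

**Invasion metrics.** Moyle classes are weighted by body-size class into a
body-mass-corrected abundance. Per site, the *invasion degree* is the share
of community abundance contributed by exotic species,

    D = Σ abundance(exotic) / Σ abundance(all)  ∈ [0, 1].

Per exotic species, *colonization* C (% of sampled sites occupied),
*prevalence* P (mean relative abundance % where present), and the
*invasiveness index* I = C × P rank the species driving the invasion.

**Drivers.** Livestock units (0.01·poultry + cattle + 0.1·sheep +
0.5·pigs), inverse-distance interpolation of monitored covariates, 10-km
radius aggregation, a seven-parameter eutrophication proxy (high = clean),
and a bounded river-fragmentation index over the migration barriers
reachable within 10 km along the network:

    F = (2/π) · arctan( Σ_b category_b / distance_b )  ∈ [0, 1).

**BRT protocol.** Boosted regression trees (≥ 1000 trees, bag fraction
0.25) with variable importance (VI, normalized to sum 100), VI < 7 deletion
and redundancy collapse, partial-dependence effect directions, Moran's I on
the residuals over Voronoi-adjacency weights, and — where spatial
autocorrelation is found — a neighbourhood autocovariate refit kept only if
it cross-validates better.

**Variance decomposition.** VIF > 8 screening within driver groups,
variation partitioning of adjusted R² across four groups (Geography,
Climate, Human factors, Land use) into 15 unique/shared fractions plus
residual with 999-permutation tests of the unique fractions, and redundancy
analysis (RDA) of the top invasive species with 499-permutation axis tests.
Both are implemented from linear algebra and cross-checked against the R
`vegan` package in the test suite.

## Worked example

```bash
fishinvasion run-all --seed 7 --out outputs/
```

simulates the default scenario (400 sites on a 200 × 200 km landscape,
15 native and 8 exotic species, spatially correlated driver fields) and runs
every stage. Typical output:

```
invasion degree BRT: cv_r2=0.810
  VI  63.7  eutrophication (positive)
  VI  24.9  altitude (negative)
  VI  11.4  temperature (positive)
varpart adj R2 = 0.8047; unique p: {'Geography': 0.161, 'Climate': 0.001,
  'Human factors': 0.001, 'Land use': 0.253}
RDA axes: [35.92, 4.71] % of variance, p = [0.002, 0.002]
```

Reading: exotic share rises toward warm, nutrient-enriched lowlands — the
protocol retains eutrophication, altitude and temperature after VI
screening and reports their effect directions from the partial-dependence
curves; the permutation tests flag the Climate and Human-factors groups as
carrying significant unique variance, while the heavily shared altitude
gradient leaves Geography without a detectable unique fraction. `outputs/` contains the invasiveness
table, per-site invasion degrees, the JSON model report (VI, directions,
CV R², reduction log, Moran results), the variance fractions and RDA scores.

The Python API mirrors the CLI: `fishinvasion.generate_landscape`,
`sample_communities`, `invasiveness_rank`, `run_brt_pipeline`,
`variation_partition`, `rda_fit`, … (see `docs/methods.md` for the science
and every default).

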