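# Methods

This note documents the models and procedures implemented in `fishinvasion`,
the choices made where the methodology was genuinely open, and what the
synthetic scenarios do and do not establish.

## Invasion metrics

Surveys record fish abundance in ordinal Moyle classes (0 = absent, 1–5).
Classes are converted to a *body-mass-corrected abundance* as
`class midpoint × body-size weight`. The original class-to-abundance
midpoints are not standardized across surveys, so the package ships a
documented default — geometric midpoints (0, 2, 8, 32, 128, 512) and size
weights 1/2/4 for small/medium/large — and accepts any positive, monotone
table (`MoyleWeightConfig`). All metric invariants (bounds, monotonicity,
scale invariance of the invasion degree) hold for any such table.

Per site, the **invasion degree** is the share of community abundance
contributed by exotic species, in [0, 1]; a site with no fish has an
*undefined* (missing) degree, never 0. Per species, **colonization** is the
percentage of sampled sites occupied (sites with no fish at all are excluded
from the denominator), **prevalence** is the mean relative-abundance
percentage over occupied sites, and the **invasiveness index** is
`colonization × prevalence` (range 0–10 000). The ranking sorts by
descending index, breaking ties by descending colonization and then species
label. Recomputing the index from the published top-10 table's printed
two-decimal columns reproduces every printed index within 0.1 (the printed
values were evidently rounded from unrounded intermediates; the Amur
bitterling row is exact at two decimals).

## Driver engineering

* **Livestock units**: 0.01·poultry + 1·cattle + 0.1·sheep + 0.5·pigs.
* **River fragmentation** uses migration barriers in four categories (1
  small jump, 2 high jump, 3 minor dam, 4 major dam; the numeric coding
  follows the listed order). For the barriers reachable within a 10 km
  along-network cutoff the index is

  `(2/π) · arctan( Σ_b category_b / distance_b )`,

  which is 0 with no reachable barrier and approaches 1 as barriers get
  closer or more severe. The inverse-tangent form is the unique bounded
  reading of the published formula (a plain tangent is unbounded and cannot
  satisfy the stated [0, 1] range). Multiple barriers enter through the sum
  of category/distance terms, which preserves the bounds and reduces to the
  single-barrier form; `nearest` and `mean_max` aggregation modes are
  available in `FragmentationConfig`. Distances are floored at a
  configurable ε (default 0.01 km) so a barrier at the site stays finite.
* **Interpolation** of point-monitored covariates is deterministic
  inverse-distance weighting (default power 2), exact at sample locations.
  It replaces Bayesian spatial smoothing deliberately: the package's subject
  is the analysis chain, and the interpolator is a pluggable, reproducible
  surface with no tuning state.
* **Radius aggregation** computes mean/min/max/sum-density over points
  within a 10 km disc; an empty disc yields a logged missing value. Basin
  cropping is out of scope; the radius variant is applied uniformly.
* **Eutrophication proxy**: seven water-quality parameters (oxygen
  saturation, BOD, COD, NH₄, NO₃, total P, E. coli) are each scored 0–100 by
  linear interpolation between configurable pristine and degraded reference
  concentrations; the station score is the mean of available subscores,
  oriented high = clean. The published index construction is not reproduced
  in the source literature available to us, so the composite is declared and
  fully configurable; only monotonicity and orientation are load-bearing.

## BRT protocol

Gradient-boosted regression trees (scikit-learn) with at least 1000 trees,
learning rate 0.01, tree depth 3, and 25% of sites withheld from each tree
(`subsample = 0.75`). Variable importance (VI) is split-improvement
importance rescaled to sum 100.

**Cross-validated R²** is the deviance explained on a genuinely withheld 25%
of sites, computed by refitting the model without them. The per-stage
out-of-bag losses reported by the boosting implementation are *not* used:
because each stage's out-of-bag points were in-bag for earlier trees, those
losses track training loss (on pure noise they would report ~0.7 "deviance
explained" where a true holdout shows ~0). The holdout refit is honest and
conservative, at the cost of one extra fit per scored model.

**Variable reduction**: (1) delete all variables with VI < 7 (on the
normalized 0–100 scale) and refit, iterating to a fixed point; (2) for
variable pairs with |Spearman ρ| ≥ 0.8 and the same effect direction, drop
the lower-VI member unless the CV R² falls by more than 0.02. Both
thresholds are configurable and every step is logged; this makes the "expert
judgement" step mechanical and reproducible.

**Effect direction** is the sign of the least-squares slope through the
partial-dependence curve; a curve whose counter-trend movement exceeds 30%
of its total movement is reported `mixed`.

**Spatial autocorrelation (SAC)**: residuals of the reduced model are tested
with Moran's I on row-standardized Voronoi-adjacency weights (Delaunay dual;
collinear geometries fall back to k-nearest neighbours). The test is
two-sided around the analytic expectation −1/(n−1), so negative SAC is
detected as well; both a Cliff–Ord normal approximation and a permutation
p-value are available. If SAC is significant (α = 0.05), an autocovariate —
the inverse-distance-weighted mean of the response over each site's Voronoi
neighbours — is added and the model refit; the better-CV R² model is kept,
and the final residuals are re-tested to confirm |I| decreased. The reported
`sac_share` is the autocovariate's VI in the final model; the CV R² gain
from adding it is reported alongside as an alternative deviance-based share.

## Variation partitioning and RDA

Implemented from linear algebra (least squares + SVD), not wrapped around an
ordination package; the R `vegan` implementation serves as an independent
cross-check in the test suite and agrees to 1e−8 on shared fixtures.

Within each driver group, collinear variables are screened by iteratively
dropping the highest VIF until all VIF ≤ 8 (exact ties drop the later-listed
column). The adjusted R² is the Ezekiel correction
`1 − (1 − R²)(n − 1)/(n − p − 1)` with `p` the rank of the centred design.

**Partitioning** fits all 15 non-empty unions of the four groups, adjusts
each R², and solves the inclusion–exclusion system for 15 unique/shared
fractions plus the residual. Shared fractions may legitimately be negative
(adjusted-R² arithmetic); the Euler–Venn export clamps *display* areas at
zero but never the table. The fractions close the full-model identity to
1e−10 by construction of the linear solve.

**Unique-fraction tests** use permutation ANOVA (default 999 permutations):
F from the residual sums of squares of the conditioning vs. full model, with
the null generated by permuting residuals of the conditioning model
(Freedman–Lane). Raw-permutation is a config alternative; the residual
scheme was chosen for its better small-sample level. p = (exceedances + 1)/
(permutations + 1).

**RDA** regresses the centred site × species matrix on the centred drivers
and takes the SVD of the fitted values; eigenvalues use the n − 1 divisor so
inertia is the covariance trace. An optional Hellinger transform of the
species matrix is a config switch (off by default). Scores follow the
correlation-biplot convention by default (scaling 2), with driver arrows as
correlations between each driver and the orthonormal constrained axes. Axis
significance (default 499 permutations) is tested sequentially: axis k
conditions on the first k − 1 observed axes by residualizing both matrices,
then permutes response rows and compares the leading pseudo-F
`λ₁ / (RSS_residual / (n − 1 − rank X))`.

Null calibration: over 1000 simulated null datasets, both permutation tests
hold their empirical type-I error within [0.03, 0.07] at α = 0.05 (the
calibration experiments use 199 permutations per dataset, an exact 5% level
under exchangeability, to keep the experiment cheap; operational defaults
remain 999/499).

## Synthetic scenarios

The generators reproduce the statistical structure the analyses assume, at
desk scale (hundreds of sites rather than thousands):

* **Landscape** (default 400 sites on 200 × 200 km): each driver is a
  deterministic trend in coordinates/altitude plus a Gaussian random field
  with exponential covariance (correlation length 50 km). Default gradients
  encode the study system's geometry — warm, nutrient-enriched, heavily
  farmed lowlands with less precipitation and more upland fragmentation.
* **Species pool**: Gaussian niche responses; exotics biased toward warm,
  enriched lowland optima, natives spread across the gradient.
* **Communities**: expected abundance × gamma multiplicative noise
  (negative-binomial-style overdispersion, variance 0.5), binned to Moyle
  classes at geometric breakpoints (1, 4, 16, 64, 256).
* **Rivers and barriers**: dendritic binary tree with uniform random edge
  lengths; barriers placed Poisson(density × length) per edge with
  configurable category probabilities.

The *planted-recovery* scenario decouples eutrophication and temperature
from the altitude gradient and lets exotic niches load only on those two
drivers (eutrophication sharper, echoing the empirical ordering), with
optima beyond the upper end of the fields so the planted effects are
monotone positive. The *planted-SAC* scenario adds a smooth spatial field to
a driver-driven response, producing residual autocorrelation that only the
autocovariate can absorb.

What passing these scenarios shows: the chain recovers planted effect
structure, holds its test levels, and corrects planted residual SAC. What it
does not show: performance on real survey data, whose sampling biases,
detection error, zero-inflation and non-Gaussian niche shapes the generator
does not emulate; and the published national-scale model outputs are not
reproducible here because the underlying data are not public — the synthetic
scenario magnitudes are design guides, not estimates.

## Numerical choices and degenerate inputs

Random fields use a Cholesky factor with 1e−8 diagonal jitter. All
generators and fits are deterministic under their seeds. Constant responses
refuse to fit (flagged degenerate); zero-variance residuals make Moran's I
undefined (raised); sites with no fish propagate as missing, never zero.
Exact collinearity resolves deterministically (later-listed column drops
first). Least-squares fits use `lstsq`/pseudo-inverse, so rank-deficient
designs degrade gracefully with a logged reduced rank.

## Problem sizes

Default scenario 400 sites, 15 natives + 8 exotics; recovery experiments
300 sites × 20 seeds; calibration experiments 1000 datasets of n = 40 with
199 permutations each. These sizes give stable medians and tight calibration
intervals while keeping a full run in minutes on one CPU.
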