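# Methods

This note records the statistical model, the numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Spatial model

Each chemistry variable (isotope ratio or log trace-element intensity) is
modelled independently, per genus, as a GP over WGS84 longitude/latitude
degrees:

* **Mean**: a constant, learned jointly with the covariance parameters
  (initialized at the training mean).  Fixing it at the training mean is
  available via `GPConfig(learn_mean=False)`.
* **Covariance**: Matérn with smoothness ν ∈ {0.5, 1.5, 2.5}, default 2.5
  (twice-differentiable sample paths — smooth enough for climate-driven
  isotope surfaces, rough enough for soil geochemistry).  The distance is
  anisotropic Euclidean in degrees with independent lon/lat lengthscales;
  no great-circle kernel and no projection.  At the study latitudes an
  east–west degree is shorter than a north–south one by cos(lat); the
  learned longitude lengthscale absorbs this compression, which is exactly
  what per-axis scaling parameters provide.  A single shared lengthscale
  (`anisotropic=False`) is available, e.g. for verification-style models.
* **Noise**: homoscedastic per variable.  Predictions report the **total**
  variance — epistemic (kriging) variance plus noise — because a test
  sample carries its own measurement/biological noise.

Chemistry is standardized per training split (mean/sd, n−1 convention)
before fitting; the frozen parameters are applied to held-out samples and
to any grid predictions.  Samples missing a variable are dropped from that
variable's training pairs only.

### Hyperparameter optimization

Exact marginal likelihood, full-batch Adam on log-parameters (the mean on
its natural scale):

| setting | value | note |
| --- | --- | --- |
| learning rate | 0.01 | |
| schedule | cosine warm restarts, period 20 | lr decays to ~0, then resets |
| early stopping | patience 5 (iterations without a new best) | best-seen parameters returned |
| iteration cap | 500 | |
| init | lengthscales 1°, signal 1, noise 0.1, mean = ȳ | standardized units |
| jitter | 1e−6 on the kernel diagonal | fixed, not tunable |

Gradients are analytic (the Matérn radial derivative has a finite
(1/r)·dK/dr limit at r = 0 for ν ≥ 1.5; ν = 0.5 uses a guarded division).
The optimization is deterministic: same data and config give bit-identical
hyperparameters.  Tests cross-check the predictive equations against an
independently coded dense solver at 1e−8 and verify median lengthscale and
noise recovery within ±50% on fields simulated from the model class
(n = 200, 20 seeds).

## Verification

With independent variables given location, the normalized squared residual
S(x) at a candidate cell is χ²(m); missing test-sample variables simply
reduce the degrees of freedom.  The territory p-value is the maximum of
per-cell p-values over the territory's grid cells (no continuous
optimization between cells — finer resolution is available by rebuilding
the grid), computed through the survival function for stability at large S.
Rejection uses the strict rule p < α.

Because the true location's p-value is Uniform(0, 1) under a correct model
and the maximum can only exceed it, the test is conservative: the type-I
error is at most α regardless of territory shape.  The oracle simulation
(predictive model = generating model) verifies this with 500 replicates.

## Determination

Posterior over grid cells per Bayes' rule, computed entirely in log-space
with log-sum-exp normalization (a 20-density product underflows in linear
space).  Components:

* **Prior**: uniform over masked cells within 300 km (haversine) of the
  *nearest* reference sample, zero elsewhere — determination is only
  attempted where reference data exist.
* **MAP**: highest-posterior support cell; ties break to the lowest
  row-major cell index (south-to-north outer, west-to-east inner — fixed
  across the package so every argmax is deterministic).
* **Credible region**: cells accumulated in descending posterior order
  (ties by ascending index) until the nominal mass is reached.  This is
  the minimum-cardinality set reaching the level; among equal-size sets it
  carries the highest mass (the highest-posterior choice).  Tests verify
  equivalence to exhaustive subset search on small posteriors.
* **Geographic metrics**: great-circle distances use the haversine formula
  with the IUGG mean Earth radius 6371.0088 km.  Cell areas use the
  spherical-rectangle approximation (res·111.195 km)²·cos(lat), adequate
  at 0.2°.  *Efficiency* is the region's total area; *coverage* asks
  whether the truth's nearest grid cell is in the region.
* **Uncertainty map**: Σⱼ ln σ̂ⱼ²(x) per cell; cells below the 25th
  percentile are "low", above the 75th "high".  If the percentiles
  coincide (degenerate spread) every cell is classified "mid".

When truth is drawn from the prior and the model is correct, the credible
region's coverage is ≥ the nominal level by construction (over-coverage
expected from cell discreteness); the oracle experiment confirms this with
1,000 replicates.

## Attribution

The attributed function is the MAP (longitude, latitude) pair — one scalar
per axis.  Coalition values replace absent features with background rows
(default: the training split) and average the model output.  Exact
enumeration of all 2^m coalitions is used for m ≤ 12; above that, an
antithetic permutation-sampling estimator (each sampled permutation is
paired with its reverse).  Both satisfy local accuracy exactly because
permutation chains telescope.  Grid discreteness makes the outputs step
functions; Shapley values remain well defined, but small attributions
should be read against the estimator noise, and no claim is made that
orderings replicate any particular fitted model's ranking.

## Synthetic worlds

The generator emulates the structure of the reference data, not its
biology:

* **Fields**: zero-mean Matérn Gaussian random fields per variable, drawn
  by dense Cholesky factorization over the masked cells (capped at 5,000
  cells; the factorization is cached across variables sharing kernel
  parameters).  Defaults — lengthscale 2°, signal variance 1, noise sd
  0.25, ν = 2.5 — are chosen so fields have realistic regional-scale
  autocorrelation and a noise-to-signal ratio under which the pipeline's
  behavior is informative; real per-variable ranges and noise levels are
  unknown (the published record gives only qualitative statements, e.g.
  short trace-element ranges), so these values are for testability and are
  not biological estimates.
* **Sampling**: cluster centers placed sequentially by rejection sampling
  with consecutive centers 100–250 km apart (retry cap 1,000, then an
  error); three trees per cluster at masked cells within 25 km of the
  center, so intra-cluster pairwise distances stay within 50 km; observed
  values are field values plus Gaussian noise.
* **Territories**: Voronoi partitions of the masked cells around seeded
  random centers (great-circle metric, ties to the lowest center index).
* **Reference fixture**: per-country/genus counts equal the published
  collection exactly (929 rows); coordinates are drawn inside per-country
  Voronoi territories on the study bounding box (15–39.5°E, 46–68.3°N) and
  chemistry comes from a seeded world at 0.5° resolution.  Only the counts
  are real — the fixture must never be used as measurement data.

Every artifact is a pure function of (parameters, seed).

What passing oracle tests shows: the test statistics and region
constructions deliver their guarantees *when the model class is correct*.
What they do not show: performance under real-world misspecification —
inter-element correlation, non-stationary isoscapes, preferential
sampling, or measurement drift.  The fitted-model experiments
(cross-validation, accuracy matrices) quantify GP estimation error only on
worlds drawn from the assumed class.

## Experiment drivers and problem sizes

Cross-validation uses plain random folds (no stratification), refitting
standardization and GPs per fold, and reports the mean ± sd of per-sample
MAP great-circle errors, plus mean credible-region efficiency and
coverage.  Verification matrices test every (sample, territory) pair;
finer-scale claims (admin units, concession tiles of 0.5° or 0.25°)
replace an incorrect country claim with the unit containing a uniformly
drawn in-country cell, and a correct claim with the truth's unit.
Sensitivity is reported both per-pair (unweighted over declared
territories) and per-sample (test-count weighted), since pooled summaries
depend on that choice.  Accuracy-matrix clustering uses average linkage on
the symmetrized accuracy d(i,j) = (M[i,j]+M[j,i])/2.

Shipped experiments run on 30×30 (tests) to 50×45 (fixture) grids with
panels of 2–23 variables and tens of training samples — sizes chosen so
the full suite and the acceptance script each complete in minutes on one
CPU while keeping every Monte-Carlo margin (3 standard errors) meaningful.

## Known limitations

* Cross-variable independence is assumed everywhere (test statistic,
  likelihood); correlated residuals would make the χ² reference
  distribution liberal.
* No inducing-point or spectral approximations: training is O(n³) per
  variable and field simulation is dense-Cholesky-bound.
* Region membership is by cell center; boundary-straddling cells follow
  the center, and overlapping claim polygons are rejected rather than
  resolved.
* The CLI's GeoJSON path supports polygons/multipolygons with a
  `territory_id` property only; no reprojection, no shapefiles.
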