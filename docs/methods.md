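# Methods

## Index construction

The composite index averages four subindices, each a structural
variable rescaled linearly between a young and an old reference median
and clipped to [0, 1]. Choices and their reasons:

- **Medians, not means**, define the reference bounds: reference sets
  are small and structural variables are right-skewed, so medians are
  robust to outlier stands. Even-sized sets use the midpoint of the two
  central order statistics.
- **The dbh cuts**: stems enter the variables only above 5 cm dbh
  (strict inequality; a 5.00-cm stem is excluded), and the large-tree
  class is dbh ≥ 40 cm (inclusive). Both thresholds are keyword
  arguments on `compute_stand_structure`.
- **Plot area defaults to 0.1 ha** and is configurable; inventory plot
  geometry varies between schemes and only densities depend on it.
- **The young reference set** defaults to stands of age ≤ 30 years
  (configurable). The lower end is not restricted: excluding stands
  younger than 10 years changed nothing in our synthetic experiments
  and the inclusive reading is the simpler contract.
- **Decreasing variables** (live stem density falls with age) need no
  special case: with `x_old < x_young` the signed rescaling already
  maps the young median to 0 and the old median to 1, and clipping
  bounds it. This is algebraically equivalent to an absolute-value
  formulation on the clipped range.

## The ε-logit transform

Index values of exactly 0 or 1 have no logit. Following the standard
treatment of proportion data in regression, boundary values are moved
inward by ε = the smallest nonzero observed value: 0 → eps_low,
1 → 1 − eps_high, where eps_low is the minimum nonzero value and
eps_high the minimum nonzero complement, each capped at 0.5. The two
boundaries get separate epsilons by default (`EpsilonRule.symmetric`
collapses them to a single ε for the simpler convention). The rule is
computed **per response** — for the composite index and for each
subindex separately when those are modelled — and recorded in the fit
metadata, so a persisted fit is exactly reproducible.

## Terrain covariates

The four DEM-derived covariates use deliberately standard algorithms;
each is a configurable approximation, since terrain pre-processing
conventions differ between GIS stacks:

- **Slope** (and aspect for the radiation model): Horn's 3×3 weighted
  finite differences on interior cells, one-sided differences on edges.
  Any nodata cell poisons its 3×3 neighbourhood.
- **Positive openness**: mean over azimuths of (90° − maximum elevation
  angle to any cell within the search radius). Defaults: 200 m radius,
  8 azimuths. Azimuths are restricted to the 8 grid directions; lines
  of sight off the grid axes would require DEM resampling and change
  results by far less than the radius choice does. A flat plane scores
  exactly 90°; cells whose line of sight leaves the grid treat that
  azimuth as open.
- **Catchment area**: priority-flood depression filling with an
  epsilon gradient (so flats drain deterministically), then D8
  steepest-descent routing with ties broken in the fixed order E, SE,
  S, SW, W, NW, N, NE. Accumulated area counts the cell itself; cells
  at the grid edge (or beside nodata) with no lower neighbour are
  outlets. Catchment area is log₁₀-transformed before standardization
  (it spans orders of magnitude and is heavily right-skewed); the
  toggle lives in the covariate table, which carries `log10_catchment`.
- **Potential solar radiation**: clear-sky annual direct insolation on
  each cell's slope/aspect — the cosine of the solar incidence angle
  accumulated over a daily/hourly loop — normalized by the horizontal-
  surface sum at the same latitude, so flat ground is exactly 1.0. No
  atmosphere, no horizon shading. Defaults (every 5th day, 15-min
  steps) agree with a day-by-day, 3-min integration to < 1%. Latitudes
  beyond ±66.5° (polar day/night) are rejected.

Snow depth and warmth index are pass-through inputs (1-km climate
grids resampled by nearest neighbour); the warmth index itself is
Σ (T_month − 5 °C) over months above 5 °C.

## The hierarchical model and its sampler

The varying-slope model is linear in 16 fixed effects once the
quadratic rate equation is substituted into the age line: intercept,
age, six age·x_k and six age·x_k² columns (squares of the
*standardized* covariate, which stabilizes the quadratic estimates),
and indicators for survey periods 1 and 2 (period 3 = reference). The
intercept is common to all plots; plot identity enters only through a
Gaussian random intercept.

- **Priors**: N(0, 10⁶) on fixed effects; Gamma(0.001, 0.001) on both
  precisions (equivalently inverse-gamma on the variances) — the
  conventional vague JAGS idiom, chosen for full conjugacy. All are
  config-exposed; in the reference analysis prior changes did not move
  the estimates, and we observe the same insensitivity on synthetic
  data.
- **Sampler**: blocked Gibbs. The 16 fixed effects are drawn jointly
  from their multivariate-normal full conditional (Cholesky solve of a
  16×16 system per sweep), plot effects independently from univariate
  normals (vectorized over plots), variances from inverse-gammas.
- **Initial values** are overdispersed around the least-squares
  solution, scaled per coefficient by its standard error. A fixed-scale
  start (e.g. N(0, 4) on every coefficient) is catastrophic here
  because design columns span three orders of magnitude — age
  interaction columns have SDs near 100 while period indicators have
  SD 0.4 — and chains started there spend thousands of sweeps escaping
  a regime where the plot-effect variance absorbs the misfit. The
  `init_sd` knob (default 2) controls the overdispersion multiple.
- **Burn-in** defaults to 1000 sweeps (the reference analysis used
  100; that is reachable via `FitConfig(burn_in=100)` but short
  burn-ins are risky for a bespoke sampler). Chains: 3, seeded
  `seed + chain index`. No thinning. If any R̂ ≥ 1.1 the chains are
  extended by another `iterations` sweeps, up to
  `max_extension_rounds`, then flagged not-converged.
- **R̂** is the classic Gelman–Rubin factor
  √(((n−1)/n · W + B/n) / W) over whole chains; the suite cross-checks
  it against an independent implementation (which uses the
  rank-normalized split variant, hence loose agreement).
- **Storage**: fixed effects and the two SDs are stored per draw; plot
  random intercepts are summarized as running posterior means only.
  Storing thousands of plot effects per draw costs hundreds of MB and
  nothing downstream consumes their posterior spread — prediction and
  R² deliberately exclude plot effects.

## Prediction and mapping

Maps use posterior-mean parameters by default (`params("median")`
switches to medians; mean- and median-based t₀.₅ are nearly identical,
r > 0.99, in both the reference analysis and our synthetic runs). The
age at target index has the closed form (logit(q) − β0)/coeff for a
positive rate; the implementation still root-solves by bracketing
(and the tests pin the two against each other at 1e−6) because the
bracketing form is what generalizes if the age line ever becomes
nonlinear. Ages are searched on (0, 1000] years; beyond that the cell
is reported *unreachable*, encoded in rasters as the sentinel −1.0
(distinct from nodata, recorded in the pipeline manifest). How sites
with a non-positive development rate should be reported is a genuine
convention choice; the sentinel keeps them distinguishable from
missing data. Covariates are clamped to the training 2.5–97.5%
quantiles before prediction to keep the quadratic rate model inside
the data envelope.

## Validation

R² is the squared Pearson correlation between the ε-logit of the
observed index and the fixed-effect linear predictor *including*
period effects and *excluding* plot effects, so it measures what the
environmental model explains, not what plot identity memorizes.
Holdout CV refits on a random 90% of sample rows and scores the held
10%, repeated (100× by convention; tests use fewer repetitions with
shortened chains to stay within time budgets — the machinery, not the
replication count, is what the tests establish). Splits are by row:
repeated measurements of one plot can land on both sides, matching the
reference procedure; group the rows by plot upstream if that leakage
matters for your question. The ε rule and covariate scaler are refit
on every training split.

The recovery harness closes the loop on the sampler: simulate from
known parameters, fit, and report per-parameter bias and pooled 95%
credible-interval coverage, excluding (and counting) non-converged
replicates.

## The synthetic world

The generator's defaults are a stated world, fixed once:

- covariate marginals are normal stand-ins — snow depth 100 ± 40 cm,
  warmth index 110 ± 30 °C·month, slope 20 ± 10°, openness 75 ± 15°,
  log₁₀ catchment 3 ± 0.8, relative radiation 1.0 ± 0.1 — plausible
  for temperate Japan but **not** fit to unpublished inventory
  marginals; the copula correlations (−0.57, −0.62) and the
  concentration of stand ages near 50 y are the features the source
  data actually constrain. With normal marginals the copula correlation
  is exactly the Pearson correlation, which is why the fidelity test
  can demand ±0.02.
- true parameters: β0 = −4, β1 = 0.03/y (index 0.5 near age 130 at
  average covariates, matching the ~150 y the field expects for high
  index values), small mixed-sign linear and quadratic covariate
  effects, period offsets −0.5/−0.25, σ_plot = 0.3, σ_resid = 0.5.
- plots are measured in 1–3 consecutive periods (5%, 55%, 40% — the
  approximate mix of the reference inventory), 5 years apart, ages
  lognormal(median 50 y, log-SD 0.6).
- the rate equation uses covariates z-scored **over the generated
  table**, exactly as the fit standardizes, so recovery experiments
  compare like with like.

What a green recovery test establishes: the sampler, transform,
design construction and interval calibration are correct *for data
generated by the model family*. It does not establish Japan-specific
effect sizes, spatial sampling structure (the real inventory is a 4-km
lattice with spatial autocorrelation), non-Gaussian covariate
marginals, or robustness to model misspecification.

`gen_tree_list` inverts the structure computation: gamma draws
moment-matched to the target mean/SD, rescaled to the exact sample
moments, floored just above the 5-cm cut, with the upper tail adjusted
to hit the large-tree count exactly. Densities and large-tree counts
are exact; mean and SD are within a few percent (the tail adjustment
and flooring perturb them).

## Numerical conventions

- Rasters are north-up, row-major, square cells, cell-center
  coordinates, ESRI ASCII on disk; NaN in memory ↔ nodata sentinel on
  disk. Stand ages are years since disturbance, ≥ 1.
- D8 ties: fixed azimuth order (E first, then clockwise), making
  routing deterministic.
- Depression filling adds 1e−6 m per pour-over step; negligible
  against real relief, sufficient to orient flats.
- The design matrix is checked for collinearity (condition number
  > 1e10 errors out); an all-constant response errors out.
- All randomness flows from integer seeds through
  `numpy.random.default_rng`; chain c uses seed + c, CV repetition r
  refits with seed + r, recovery replicate r simulates with
  generator seed + r and fits with fit seed + 1000r. Identical seeds
  give byte-identical outputs.

## Known limitations

- Openness supports only grid-aligned azimuths (4 or 8).
- The radiation model omits diffuse radiation, atmosphere and horizon
  shading; it is a *relative potential* insolation index.
- Single-flow-direction (D8) routing concentrates flow unrealistically
  on divergent hillslopes; acceptable for a log-transformed covariate,
  wrong for hydrograph work.
- No spatial autocorrelation in residuals, no spline/cubic rate
  models, no model selection — the quadratic varying-slope model is
  the scope.
- Full posterior propagation to maps (per-cell credible intervals) is
  not implemented; maps are point-estimate maps.
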