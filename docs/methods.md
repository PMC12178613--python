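# Methods

## Model

The package links microbial cell volume to Michaelis–Menten uptake traits
through three deterministic power laws on canonical units (mol, g dry
weight, L, h, µm³):

* cell-specific maximum uptake rate: `V_max = a · V_cell^b`
  (mol S cell⁻¹ h⁻¹);
* dry weight per cell: `w = α · V_cell^β` with defaults
  `α = 10^−12.244` g µm^−3β and `β = 0.920`, giving the dry-weight-specific
  rate `V_maxDW = (a/α) · V_cell^(b−β)`;
* affinity trade-off: `K_m = c̄ · V_maxDW^d` with the compound prefactor
  `c̄ = c·w^d`.

A lognormal cell-volume prior `V_cell ~ LN(μ, σ²)` (defaults μ = −0.74,
σ = 1.49, the moments of a 5380-volume prokaryotic compilation whose
observed quartiles, 0.218 and 1.048 µm³, are carried along for coverage
statistics) then induces lognormal distributions for both traits by change
of variables:

    ln V_maxDW ~ N( ln(a/α) + (b−β)μ , (b−β)²σ² )
    ln K_m     ~ N( ln c̄ + d·[ln(a/α) + (b−β)μ] , d²(b−β)²σ² )

The likelihood of a record set is the sum of the two log-densities over all
observed values; the two variables are treated as conditionally independent
given the parameters, so records reporting only one variable contribute one
term (an `exclude_partial` switch drops them instead). Because the
lognormal log-density is quadratic in ln x, the data enter only through
counts, sums and sums of squares of the log values; the sampler precomputes
these sufficient statistics, making each iteration O(1) in the data size.

Note an internal feature of the trade-off equation as used here: folding
`w^d` into `c̄` treats the per-cell weight as a constant even though `w`
varies with `V_cell` through the weight–volume law. The induced K_m
distribution inherits this simplification. We implement the equations as
composed (so `K_m(V_cell) = c̄·V_maxDW(V_cell)^d` exactly) rather than
"correcting" them, and the composition identity is asserted in the tests.

## Inference

`(a, b, c̄, d)` are sampled by random-walk Metropolis–Hastings:

* initialisation by moment matching: the sample mean/sd of `ln V_maxDW` and
  `ln K_m` invert the moment equations in closed form
  (`b = β + sd(ln V_maxDW)/σ`, positive root `b > β`, the branch consistent
  with the chemotroph estimates; `d = sd(ln K_m)/sd(ln V_maxDW)`; prefactors
  from the means). Moments determine `(b−β)²` only, so the sign choice is
  explicit and tested.
* proposals: independent normals on the natural scale, standard deviation
  frozen at 5% of each parameter's |initial value|; proposals outside
  `{a > 0, c̄ > 0}` are rejected. Both all-at-once (`update="joint"`, the
  default) and coordinate-sweep (`"componentwise"`) updates are provided.
* chain length: 100 000 iterations with the first 20 000 discarded as
  burn-in by default; posterior means and standard deviations are the point
  estimates.

### Priors

Priors are improper: flat on the exponents `b` and `d`, and scale-invariant
(∝ 1/a, ∝ 1/c̄) on the positive prefactors (`prior_kind="log_flat"`, the
default). A variant flat on the natural scale of all four parameters —
acceptance ratio exactly the likelihood ratio — is available as
`prior_kind="flat"`, but it is *not* innocuous: flat-in-c̄ corresponds to a
prior weight `exp(m_K − d·m_V)` on the induced log-means, and since the
V_maxDW log-mean sits around −6, this tilts the posterior of `d` upward by
several hundredths and inflates `c̄` substantially. We verified the effect
against an exact importance-sampling representation of the same posterior
(conjugate normal blocks reweighted by the parameter-space Jacobian): the
sampler and the oracle agree, so the tilt is a property of that prior, not a
sampler artefact, and under it the 95% credible intervals undercover the
generating parameters in recovery experiments (≈65–80% instead of ≈95%).
The log-flat default removes the tilt and calibrates the intervals.

### Diagnostics

Convergence is assessed quantitatively: effective sample size (via arviz)
and a split-chain variance-ratio statistic, with warnings below ESS 400 or
above ratio 1.05; the full chain is serialised as CSV for visual
inspection. A single 100k joint-update chain at the 5% proposal scales has
ESS of order 30–100 for this posterior, which leaves visible Monte-Carlo
noise in interval endpoints; where quantile accuracy matters (recovery
experiments, the acceptance script) we therefore run componentwise updates
and pool 4 chains started from the same initial point with seed offsets of
1000. Pooled quantiles reproduce the exact-oracle intervals.

## Synthetic data

`generate_dataset` draws cell volumes from the size prior and pushes them
through the forward maps, with the chemotroph posterior-mean parameters
(a = 4.64e−15, b = 2.70, c̄ = 1.83e−2, d = 1.254) and n = 161 records as the
default conditions. Two coupling modes:

* `independent` (default): each record's V_maxDW and K_m come from separate
  volume draws — zero log-space correlation, exactly the factorised
  structure the likelihood assumes. Recovery experiments use this mode, so
  the estimator is correctly specified under it.
* `coupled`: one volume draw feeds both maps (log-correlation 1 at zero
  noise). This is what a strictly size-driven world would produce, and it is
  the mode in which the observed near-zero V_maxDW–K_m correlation of real
  chemotroph compilations *conflicts* with the size-driven model — the
  generator exposes that tension rather than hiding it.

Multiplicative lognormal noise per variable is available but defaults to 0:
the induced-distribution model contains no explicit error term, so nonzero
noise is an extension for realism studies (its effect on the marginal sd is
a quadrature inflation, asserted in the tests). Group labels are assigned
round-robin and are cosmetic unless per-group log offsets are configured.
What the generator does **not** emulate: per-reference unit heterogeneity,
temperature/pH effects, phylogenetic structure, or the residual scatter of
real compilations around the power laws. Passing recovery tests therefore
demonstrates internal consistency of the estimator, not field validity of
the scaling model.

## Records, units and filtering

CSV ingest accepts a wide schema (canonical-unit `vmax_dw`/`km` columns) or
a long schema (`value`, `unit`, `variable`) with unit standardisation at the
I/O boundary: amounts mol/mmol/µmol/nmol, rate bases per g or mg of dry
weight or protein or per cell, times per h/min/s/day, concentrations as
mol L⁻¹ variants or molarity shorthand. Per-protein values use a
configurable protein:dry-weight mass ratio (default 0.55 g/g, a typical
bulk composition figure); per-cell values need a dry weight per cell or a
cell volume (converted through the weight–volume law). Conversions
round-trip to 1e−12 relative error.

Anomaly filtering is a documented robust-z rule replacing the black-box
filter of the original workflow: flag a record when
|log₁₀x − median| / (1.4826·MAD) > 3.5 for either variable, with IQR/1.349
and then the ordinary standard deviation as fallback scales when the MAD or
IQR degenerate. The kept/removed sets always partition the input and
removed records are reported for audit. Filtering is not idempotent in
general (robust statistics are recomputed on the kept set); the tests
assert idempotence only on fixtures where it holds.

## Descriptive statistics

* Mann–Whitney U: two-sided, normal approximation with continuity and tie
  corrections (scipy); an all-tied pooled sample returns p = 1 with a
  warning. Rank-based, hence invariant under monotone transforms (tested).
* Normality suite on log values: Shapiro–Wilk (scipy), Kolmogorov–Smirnov
  with the Lilliefors estimated-parameter null, and Anderson–Darling
  (statsmodels), since the hypothesised normal's moments come from the
  sample itself.
* Hartigan's dip statistic: own implementation of the published iterative
  greatest-convex-minorant / least-concave-majorant construction (no
  maintained Python implementation is available in this stack), validated
  in the tests against an exact linear-programming formulation of the dip
  on small samples. The bootstrap p-value uses the uniform null (n_boot
  default 10 000), the standard convention.
* Log–log regressions: OLS of log₁₀K_m on log₁₀V_maxDW overall and per
  functional group (groups need > 3 pairs; smaller groups are reported as
  skipped). Adjusted R² = 1 − (1−R²)(n−1)/(n−2). Reduced-major-axis slopes
  are available as an option for trade-off-literature comparisons.
* Bivariate fit: sample mean and covariance of the log₁₀ pairs with the
  95% Mahalanobis ellipse at χ²₂(0.95) = 5.991.
* Cell-volume coverage: every observed V_maxDW and K_m is inverted through
  the fitted power laws; the statistic is the fraction of estimates inside
  the prior's observed interquartile interval [0.218, 1.048] µm³ plus the
  min–max range. For model-generated data this fraction equals the prior
  mass of the interval (≈0.40, closed form), asserted in the tests.

## Problem sizes and numerical choices

Change-of-variables checks use n = 1e5 samples (two-sample KS < 0.01); the
grid oracle for the one-parameter subproblem uses 2000 grid points against
a 60k-iteration chain; recovery experiments use 20 replicates of n = 161
with 100k-iteration chains (4 pooled componentwise chains each), chosen to
keep the whole validation suite in the minutes range on one CPU.
Consistency scans use 12 replicates per size over n ∈ {50, 161, 500, 2000}
— fewer replicates leave adjacent-size RMSE comparisons dominated by
data-draw luck. Forward/inverse map round-trips are exact to 1e−10 relative
over V_cell ∈ [1e−3, 1e4] µm³; degenerate maps (b = β, or d = 0) raise
dedicated errors rather than returning infinities, except in the likelihood,
which returns −∞ so boundary proposals can be scored. All randomness flows
through `numpy.random.default_rng` seeds; replica chains use documented
seed offsets.

## Limitations

* Real compilations violate strict log-normality (the normality suite is
  there to show it); the lognormal machinery is an approximation adopted
  for its closed-form change of variables.
* The likelihood's independence structure contradicts the coupled forward
  model; fitting coupled-mode data treats shared-volume correlation as if
  absent, and the package deliberately ships both modes to make that
  visible.
* Reproduction of published point estimates from the original literature
  compilation requires that archived dataset and its exact unit and
  outlier decisions; the robust-z filter here is a documented substitute,
  so data-dependent statistics can shift slightly.
* `c̄` absorbs a weight factor and is not decomposed into `c` and `w^d`
  by default, since no per-cell weight is identifiable from the kinetic
  data alone.
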