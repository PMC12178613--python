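# allokin

Allometric scaling of microbial Michaelis–Menten uptake kinetics: lognormal
trait distributions induced by cell size, and Bayesian inference of the
scaling exponents.

## The scientific problem

Microbial resource uptake is commonly modelled with Michaelis–Menten
kinetics,

    uptake rate = V_max · S / (K_m + S),

where `V_max` is the maximum uptake rate and `K_m` the half-saturation
constant. In phytoplankton, both parameters scale with cell volume as power
laws — `V_max = a·V_cell^b`, `K_m = c·V_max^d` — with a positive `d`
expressing a rate–affinity trade-off. For chemotrophic microorganisms
(aerobic heterotrophs, fermenters, nitrifiers, iron reducers, CO oxidisers,
…) most kinetic measurements lack any cell-size information, so these scaling
laws cannot be fitted directly.

`allokin` implements an indirect route. Prokaryotic cell volumes are
approximately lognormal, `V_cell ~ LN(μ, σ²)` (defaults μ = −0.74, σ = 1.49
from a compilation of 5380 prokaryotic cell volumes). If the power laws hold,
the dry-weight-specific rate `V_maxDW = (a/α)·V_cell^(b−β)` (using the
empirical weight–volume relation `w = α·V_cell^β`, α = 10^−12.244,
β = 0.920) and `K_m = c̄·V_maxDW^d` are then also lognormal:

    V_maxDW ~ LN( ln(a/α) + (b−β)μ , (b−β)²σ² )
    K_m     ~ LN( ln c̄ + d[ln(a/α) + (b−β)μ] , d²(b−β)²σ² )

The quadruple (a, b, c̄, d) is estimated by Metropolis–Hastings sampling of
the likelihood built from these two densities (records missing one variable
contribute a single term), initialised by moment matching and using normal
proposals with standard deviations at 5% of the initial values. The package
also ships the surrounding analysis: unit standardisation and robust-z
anomaly filtering of literature records, group medians and Mann–Whitney
comparisons, normality tests, Hartigan's dip test of unimodality (own
implementation of the published hull construction), per-group log–log
regressions, bivariate-normal fits with Mahalanobis confidence ellipses,
cell-volume back-prediction, and a synthetic-data generator that closes the
loop for parameter-recovery validation.

## Worked example

```python
from allokin import SyntheticConfig, UptakeScalingModel, generate_dataset

records = generate_dataset(SyntheticConfig(n=161, seed=1))   # synthetic compilation
model = UptakeScalingModel.from_records(records)
result = model.fit(iterations=100_000, burn_in=20_000, seed=1,
                   update="componentwise")
print(result.summary())
```

```
Uptake-kinetics scaling model: Metropolis-Hastings posterior
================================================================
records: 161   vmax_dw: 161   km: 161
draws: 80000 (after burn-in 20000)   acceptance: 0.698
----------------------------------------------------------------
 param         mean          sd        2.5%       97.5%     ESS     R^
     a    3.288e-15    6.68e-16   2.209e-15   4.815e-15     235  1.000
     b        2.529      0.0888        2.37       2.716     211  1.000
 c_bar      0.02975      0.0205    0.006147     0.08308      71  1.004
     d        1.309      0.0968       1.122       1.496     100  1.002
----------------------------------------------------------------
warning: a: low effective sample size (235 < 400)
...
```

The generating parameters here were a = 4.64e-15, b = 2.70, c̄ = 1.83e-2,
d = 1.254 (the chemotroph posterior means used as defaults throughout); each
sits inside its 95% credible interval — this dataset's b happens to land
about 1.9 posterior sds below truth. Pooling several seed-offset chains
(`MCMCConfig(n_chains=4)` with `allokin.mcmc.sample_chains`) raises the
effective sample size when tighter quantiles are needed.
`result.vcell_coverage()`
back-predicts a cell volume from every record and reports the fraction
inside the prokaryotic interquartile range [0.218, 1.048] µm³, and
`result.predict_vmaxdw(vcell)` / `result.predict_km(vcell)` evaluate the
fitted scaling curves.

A command line covers the same pipeline end to end:

```bash
allokin simulate --n 161 --seed 1 --out records.csv
allokin fit records.csv --iterations 100000 --burn-in 20000 --seed 1
allokin stats records.csv --out stats.json
allokin recover --n-reps 20 --seed 0
allokin run --input records.csv --out results/
```

`allokin run` writes the cleaned/removed record CSVs, the chain, posterior
and stats JSON, and figure-ready CSVs (marginal densities, scaling curves
with back-predicted volumes, observed and posterior-predictive confidence
ellipses), each stamped with the seed and a configuration hash.
`scripts/plot_results.py <results-dir>` renders them.

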