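# diarmap

Model-based geostatistical estimation of childhood diarrhoeal burden —
prevalence, incidence and mortality in children under 5 — at the second
administrative unit (district) level, exercised end to end on synthetic
survey worlds.

Diarrhoea remains a leading cause of child death in low- and middle-income
countries, and national rates hide most of the geographic story: a district
can sit several-fold above its country average. The standard tooling for
mapping this burden combines household-survey cluster data, a stacked
ensemble of covariate learners, a Bayesian space–time geostatistical model,
calibration ("raking") to national envelopes, and draw-based aggregation to
admin units. `diarmap` implements that whole pipeline as a tested library
plus a small CLI, for methodologists who want to study the pipeline's
behaviour under known truths rather than to re-estimate any real country.

## The model

For survey cluster *c* with `N_c` children examined and `y_c` with diarrhoea,

```
y_c ~ Binomial(N_c, p_c),      logit(p_c) = Σ_j w_j · logit(g_j(s_c, t_c)) + u(s_c, t_c)
```

where `g_j` are the prediction surfaces of component learners (penalized
linear, boosted trees, additive splines) combined by simplex weights `w`
(stacked generalisation), and `u` is a latent Gaussian field with separable
covariance

```
Cov[u(s,t), u(s',t')] = σ² · Matérn₃/₂(‖s−s'‖; ρ_s) · ρ_t^{|t−t'|} + τ² · 1[(s,t)=(s',t')]
```

Inference is empirical-Bayes Laplace on the full cell×year grid: the latent
field posterior is approximated by a Gaussian at its mode, hyperparameters
(σ, ρ_s, ρ_t, τ) maximise the Laplace marginal likelihood with weak
hyperpriors, and joint posterior draws of the prevalence surface mix over
hyperparameter values sampled from a Gaussian approximation of their
posterior. Post-estimation follows the standard chain:

* **incidence** = prevalence × 365 / 4.2 (mean episode duration of 4.2 days),
* **mortality** = incidence × country–year case-fatality rate (constant
  subnationally),
* every draw is **raked** so its population-weighted national aggregate
  matches the national envelope (logit shift for prevalence, multiplicative
  factor for rates),
* draws aggregate to admin units as population-weighted means; uncertainty
  intervals are the 2.5th/97.5th percentiles across 250 draws (default);
* inequality is quantified by unit-vs-country deviations and the
  population-weighted Gini coefficient;
* a counterfactual analysis attributes deaths averted to WASH
  (water/sanitation) and CGF (child growth failure) exposure changes via
  population-average relative risks `s(x) = 1 + x(RR − 1)` under a
  risk-independence assumption.

Because the real survey archive is not redistributable, the `worldgen`
module generates synthetic worlds with the same statistical structure —
binomial cluster counts over a logit-linear-plus-GP truth, point and polygon
records, uneven space–time coverage, heavy-tailed populations, envelope and
case-fatality tables with known relationships to the truth — so that every
downstream claim can be checked against a known answer.

## Worked example

The numbered scripts under `analysis/` run the pipeline stage by stage on a
shared desk-scale world (20×20 grid, 3 countries, 6 years, 1500 survey
records), writing tables to `results/`:

```
$ python analysis/01_simulate_world.py
world: 20x20 cells, 3 countries, 12 admin2 units, years 2012-2017
truth prevalence: mean 0.168, range [0.021, 0.706]
surveys: 1500 records (131 polygon), 37500 children examined

$ python analysis/04_fit_geostatistical_model.py
stacking weights: {'penalized-linear': 0.202, 'tree-ensemble': 0.688, 'spline-additive': 0.111}
GP hyperparameters (MAP): range 4.82 cells, sd 0.414, temporal rho 0.485, nugget sd 0.077

$ python analysis/06_aggregate_and_inequality.py
mortality Gini across admin2 units: {2012: 0.222, ..., 2017: 0.229}
largest relative mortality deviation: unit C00.A00.D00 in 2013, 42.8% above its country mean
share of units with mortality declining >10%/year: 81.5% (95% UI 66.7%-100.0%)

$ python analysis/07_counterfactual_drivers.py
deaths averted in 2017 vs 2012 exposures: 356 (95% UI 355-358)
dominant drivers across units: {'none': 5, 'CGF': 5, 'WASH': 2}
attributable fraction range across units: 64.8% - 72.9%
```

The stacking weights say the boosted trees carried most of the predictive
signal here; the GP range of ~4.8 cells recovers the simulated truth (5
cells); the Gini values say this synthetic region is moderately unequal; and
the counterfactual attributes about two thirds of remaining deaths to the
WASH and CGF risk factors combined. The same pipeline is available as one
command:

```
diarmap run-all --out scratch/run --seed 0        # or: --config my.yaml
```

with stage subcommands (`simulate`, `prep`, `stack`, `fit`, `post`,
`aggregate`, `counterfactual`, `validate`) that re-run any stage from the
saved outputs of the previous one.

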