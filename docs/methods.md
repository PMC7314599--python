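# Methods

This note documents the models and procedures implemented in `diarmap`, the
assumptions behind them, the synthetic-data generator's scope, and the
numerical choices that matter for reproducing results.

## Observation model and latent field

Cluster-level survey counts are binomial: `y_c ~ Binomial(N_c, p_c)` with
`p_c` the point prevalence of diarrhoea (three or more loose stools in 24 h)
among children under 5 at the cluster's cell and year. The linear predictor
combines a stacked ensemble mean with a latent space–time field:

```
logit(p) = Σ_j w_j · logit(g_j)  +  u,     w_j ≥ 0, Σ w_j = 1
u ~ GP(0, σ² Matérn₃/₂(ρ_s) ⊗ AR1(ρ_t) + τ² I)
```

Assumptions worth stating explicitly:

* **Matérn smoothness ν = 3/2.** Fixed, not estimated: once-differentiable
  fields with a closed-form correlation, the common default in prevalence
  mapping. Distances are measured in grid-cell units.
* **Separability.** Spatial and temporal correlation factorise. Real
  epidemic dynamics need not be separable; this is a modelling convenience
  shared with the mainstream tooling.
* **Per-cell-year nugget.** The iid term τ² sits on the grid, not on
  clusters, so posterior draws at unobserved cells carry fine-scale
  overdispersion. (A per-cluster nugget is the other defensible reading;
  the grid version keeps the latent state finite-dimensional.)
* **One region.** Countries are fitted jointly in a single region at desk
  scale. Independent per-region fits are a configuration loop, not a
  different model.

Covariates are filtered for multicollinearity before stacking by iterative
variance-inflation-factor elimination (drop the largest VIF until all are at
or below 3; ties break alphabetically for reproducibility). The filter can
run per modelling region with region-specific retained sets
(`vif_filter_by_region`); the pipeline's default is a single region at desk
scale. Polygon records are resampled to population-proportional point
pseudo-clusters (default 10 per record) with child and case totals conserved
by largest-remainder rounding — population-weighted resampling matches the
population-weighted aggregation used everywhere downstream.

## Stacked generalisation

Three learner families mirror the usual ensemble: ridge regression and a
spline-additive model on the empirical logit `log((y+0.5)/(N−y+0.5))` with
weights `N`, and gradient-boosted classification trees on case/non-case
expanded weights. Tree settings are deliberately conservative (60 trees,
depth 2, subsample 0.8, min 20 per leaf): cluster fractions are noisy
binomial observations, and an unconstrained boosted ensemble memorises
individual cells through their covariate fingerprints.

Folds are assigned by random partition stratified by survey source, so a
record is never predicted by a model that saw its own source. The simplex
weights `w` are fitted by binomial maximum likelihood on the out-of-sample
(OOS) learner logits through a softmax parametrisation; with one learner the
weight is exactly 1.

**Offset construction (important for calibration).** The fixed-effect offset
used by the geostatistical fit is the children-weighted OOS stacked logit at
observed cell-years and the cross-fitted (fold-averaged) learner surface
elsewhere. Full-data learner surfaces track the training clusters too
closely; using them as the offset deflates the residual variance estimate
and produces posterior intervals far below nominal coverage. OOS offsets
remove that leakage; the full-data surfaces are still produced and written,
as the per-learner prediction rasters.

## Inference

Empirical-Bayes Laplace on the dense cell×year grid (n up to ≈3000):

1. For candidate hyperparameters θ = (ρ_s, σ, ρ_t, τ), the latent-field
   posterior mode is found by damped Newton iterations in the standard
   `B = I + W^½ K W^½` formulation (one Cholesky per iteration; warm-started
   across evaluations).
2. θ maximises the Laplace marginal likelihood plus weak hyperpriors
   (log-normal on the range centred at a quarter of the grid extent,
   half-normal(1) on σ, half-normal(0.5) on τ, uniform(−1,1) on ρ_t),
   via Nelder–Mead (default 60 evaluations).
3. Joint posterior draws of η come from the Gaussian approximation
   `N(f̂, (K⁻¹+W)⁻¹)`. By default the draws are a mixture over 8
   hyperparameter values — the MAP plus 7 samples from a Gaussian
   approximation of the hyperparameter posterior (central-difference
   Hessian, step 0.15 on the transformed scale, eigenvalues floored at
   10⁻²) — each with its own Laplace mode and covariance. The mixture is
   what brings the 95% interval coverage of the truth surface to nominal;
   the plug-in (single-component) variant undercovers by several points and
   is retained for cheap cross-validation refits.

The inference scheme is pluggable in the sense that anything returning joint
draws of η over all cells and years can stand behind `sample_posterior`;
the dense Laplace implementation is the default and is exact-in-family at
the grid sizes used here.

## Post-estimation

* **Incidence** = prevalence × 365/4.2. The 4.2-day mean episode duration
  and 365-day year are constants of the conversion; the difference from
  365.25 is <0.07%.
* **Mortality** = incidence × CFR(country, year), constant subnationally.
  This provably understates subnational mortality inequality if case
  fatality co-varies with prevalence within countries — documented, not
  corrected.
* **Raking** is per draw, per country-year: multiplicative closed form for
  rates, a monotone logit shift (Brent root-finding, |aggregate−envelope| ≤
  10⁻¹⁰) for prevalence so values stay in [0,1]. Raking each draw rather
  than the mean keeps the uncertainty intervals honest after calibration.
  A per-country exclusion list skips calibration where envelopes are judged
  unusable. Mean-only raking and mode swaps are configuration.

## Aggregation and inequality

Unit rates are population-weighted means of cell rates, computed per draw;
summaries use the 2.5th/97.5th percentiles across draws with linear
interpolation between order statistics (the percentile estimator is not
pinned by convention; linear interpolation is numpy's default and is frozen
in the tests). Counts are rate × under-5 population per draw. Deviations
(absolute, ratio, relative-%) retain per-draw values so "higher in every
draw" statements are checkable. The Gini across units is population-weighted,

```
G = Σᵢ Σⱼ wᵢ wⱼ |xᵢ − xⱼ| / (2µ),
```

computed in O(n log n) and cross-checked against the O(n²) double loop.
Decline classification defaults to annualised change `(x₁/x₀)^{1/Δy} − 1`
with a 10%/year threshold ("total" change is the config alternative;
the two always agree in sign draw by draw). Top-risk units are taken by
descending mean mortality until their cumulative population share first
reaches 20%, boundary unit included; ties break by larger population, then
unit id.

## Counterfactuals

For a dichotomous risk factor with risk ratio RR and exposed share x, the
population-average relative risk is `s(x) = 1 + x(RR−1)` (a category list
with `s = Σ pᵢ RRᵢ` generalises it). Counterfactual deaths scale by
`Π_r s_r(x_ref)/s_r(x_obs)` under the assumption that risk factors act and
change independently; population and mortality stay at observation-year
levels. WASH (prevent) and CGF (protect) groups are reported separately and
combined; ORS (treat) is excluded from the default counterfactual because
its effect operates on case fatality, and is available behind
`include_treat`. The attributable fraction is `1 − 1/Π_r s_r`. A unit's
dominant driver is the group whose single-group averted deaths exceed half
the combined total; ties and non-positive totals label "none".

## The synthetic world

`worldgen` emulates the statistical structure the pipeline assumes:

* a regular grid with a three-level admin hierarchy of contiguous
  rectangular blocks (contiguity is all downstream aggregation needs);
* heavy-tailed under-5 population (log-normal, σ=1.5, deterministic 1.5%
  annual growth) so a few urban-like cells dominate counts;
* standardized covariates as Matérn fields (some time-varying with linear
  trends, some deliberately collinear mixtures to exercise the VIF filter);
* truth prevalence `logit(p) = β₀ + Xβ + GP + nugget` with the same
  covariance family the model fits;
* surveys: sources pinned to a single year and country, clusters sampled
  proportional to population, a configurable fraction of polygon records
  observing the population-weighted unit mean, whole survey years missing
  by design (default 20%);
* national envelopes equal to the truth's population-weighted aggregates
  times `(1+ε)`, ε ~ U[−0.1, 0.1] per measure, with CFRs constant
  subnationally and declining 2%/year — so raking has a known target and
  the mortality envelope is exactly incidence × CFR;
* risk-factor exposures with linear time trends and optional spatial noise.

What it does **not** emulate: real administrative borders, DHS sampling
weights and stratification, recall-period seasonality (deliberately not
injected), spatially varying case fatality, and cause-specific (etiology)
structure. Passing tests therefore demonstrate that the pipeline's
machinery is correct and calibrated under its own assumptions — not that
those assumptions hold for any real country.

## Validation configuration and problem sizes

The reference validation run uses a 20×20 grid, 3 countries, 6 years,
30 sources × 50 clusters × 25 children (≈1500 records), truth logit-linear
in three covariates plus a GP (range 5 cells, σ=0.5, ρ_t=0.8, τ=0.12), and
the penalized-linear + spline-additive learners. The smooth learners keep
the stacked offset's error near-stationary, so the fitted family nests the
truth and interval coverage is a meaningful check; boosted trees — although
a better point predictor in some runs — fingerprint individual cells and
make the offset error heavy-tailed, which no stationary field can represent
(their effect on calibration is visible by swapping the learner list in the
acceptance configuration). On this configuration the posterior-mean
prevalence RMSE beats the best single learner (typically 0.04 vs 0.05–0.07)
and the 95% interval coverage of the truth surface sits between 0.90 and
0.96 across seeds.

Cross-validation refits use a lighter configuration (25–30 optimizer
evaluations, plug-in hyperparameters, 60–100 draws): held-out cluster
fractions are dominated by binomial sampling noise, and the binomial
predictive intervals are wide regardless of hyperparameter uncertainty.
The unit-test parameter-recovery check runs 3 worlds at 16×16×4 with 600
clusters; `analysis/09_parameter_recovery.py` runs the full-size version
(10 worlds, 20×20×6, 1500 clusters) for anyone who wants the slower study.

## Known limitations

* Empirical-Bayes Laplace ignores skewness of the hyperparameter posterior;
  the Gaussian mixture is a first-order correction, not MCMC.
* Dense covariance limits the grid to a few thousand cell-years; larger
  grids need the usual sparse/spectral machinery, which is out of scope.
* Stacking weights are point estimates; their uncertainty is partially
  absorbed by the latent field but not propagated explicitly.
* The counterfactual inherits the risk-independence assumption and GBD-style
  external risk ratios; it is an accounting identity on those inputs, not a
  causal estimate.
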