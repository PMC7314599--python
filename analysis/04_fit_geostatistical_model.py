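#!/usr/bin/env python
"""Fit the Bayesian binomial geostatistical model and draw joint posteriors.

Estimates simplex stacking weights from the out-of-sample predictions, then
the Matern x AR1 latent field by Laplace-approximate MAP, and samples joint
posterior prevalence draws (mixing over the hyperparameter posterior).
"""

from common import make_run, publish

from diarmap.pipeline import stage_fit

run = make_run(__doc__)
world, fit, draws = stage_fit(run)

print("stacking weights:",
      {n: round(float(w), 3) for n, w in zip(fit.learner_names, fit.weights)})
gp = fit.gp_params
print(f"GP hyperparameters (MAP): range {gp.spatial_range:.2f} cells, "
      f"sd {gp.spatial_sd:.3f}, temporal rho {gp.temporal_rho:.3f}, "
      f"nugget sd {gp.nugget_sd:.3f}")
print(f"diagnostics: {fit.diagnostics}")
print(f"draws: {draws.n_draws} joint surfaces over "
      f"{draws.values.shape[0]} cells x {draws.values.shape[1]} years; "
      f"posterior-mean prevalence {draws.mean().mean():.3f}")
publish(run, "stack_weights.csv")
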