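#!/usr/bin/env python
"""Simulate the synthetic survey world.

Builds the desk-scale world (20x20 grid, 3 countries, 6 years), realises a
truth prevalence surface (logit-linear covariate effects plus a separable
Matern x AR1 space-time field), draws DHS-like cluster and polygon surveys
with binomial outcomes, and generates the national envelope/case-fatality
tables and risk-factor exposure surfaces that the later stages consume.
"""

from common import make_run, publish

from diarmap.pipeline import stage_simulate

run = make_run(__doc__)
world, truth, surveys, inputs, factors = stage_simulate(run)

n_poly = int((surveys["geometry_kind"] == "polygon").sum())
print(f"world: {world.grid.nrows}x{world.grid.ncols} cells, "
      f"{len(world.admin.units_at_level(0))} countries, "
      f"{len(world.admin.units_at_level(2))} admin2 units, "
      f"years {world.years[0]}-{world.years[-1]}")
print(f"truth prevalence: mean {truth.prevalence.mean():.3f}, "
      f"range [{truth.prevalence.min():.3f}, {truth.prevalence.max():.3f}]")
print(f"surveys: {len(surveys)} records ({n_poly} polygon), "
      f"{surveys['n_children'].sum()} children examined")
print(f"national inputs: {len(inputs.table)} country-years; "
      f"{len(factors)} risk factors")
publish(run, "surveys.csv", "national_inputs.csv", "risk_factors.csv")
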