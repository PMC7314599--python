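#!/usr/bin/env python
"""Filter covariates for multicollinearity and resample polygon records.

Applies the iterative VIF filter (threshold 3) to the covariate stack and
expands each polygon survey record into population-weighted point
pseudo-clusters, conserving child and case totals exactly.
"""

from common import make_run, publish

from diarmap.pipeline import stage_prep

run = make_run(__doc__)
world, points, retained = stage_prep(run)

print(f"covariates retained ({len(retained)}): {', '.join(retained)}")
print(f"point records after polygon resampling: {len(points)} "
      f"(children conserved: {points['n_children'].sum()})")
publish(run, "covariates_retained.csv", "surveys_points.csv")
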