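#!/usr/bin/env python
"""Convert prevalence draws to incidence and mortality, raked to envelopes.

Prevalence is raked to the national envelopes by a per-draw logit shift,
converted to incidence through the 4.2-day mean episode duration and raked
multiplicatively, then multiplied by country-year case-fatality rates to give
mortality.  Every draw's population-weighted national aggregate matches its
envelope after raking.
"""

import numpy as np
from common import make_run, publish

from diarmap.pipeline import stage_post

run = make_run(__doc__)
world, cubes = stage_post(run)

for measure, cube in cubes.items():
    m = np.nanmean(cube.values)
    print(f"{measure}: grand mean {m:.4g} "
          f"({cube.n_draws} draws, measure unit per child-year"
          f"{' (proportion)' if measure == 'prevalence' else ''})")
publish(run, "raking_factors.csv")
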