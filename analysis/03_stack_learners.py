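#!/usr/bin/env python
"""Fit the component learners of the stacked ensemble.

Fits the penalized-linear, boosted-tree and additive-spline learners to the
cluster data under a source-stratified five-fold split, producing honest
out-of-sample predictions per record and full prediction surfaces per
learner for every cell-year.
"""

import numpy as np
from common import make_run, publish

from diarmap.pipeline import stage_stack

run = make_run(__doc__)
world, points, stack = stage_stack(run)

obs = points["n_cases"].to_numpy() / points["n_children"].to_numpy()
print(f"learners: {', '.join(stack.learner_names)}")
for name in stack.learner_names:
    r = np.corrcoef(stack.oos[name], obs)[0, 1]
    print(f"  {name}: OOS correlation with observed cluster fractions {r:.3f}")
publish(run, "stack_oos.csv")
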