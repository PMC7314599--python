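#!/usr/bin/env python
"""Aggregate draws to admin units and quantify geographic inequality.

Produces population-weighted unit estimates with 95% uncertainty intervals,
unit-vs-country deviations, Gini coefficients per measure-year, annualised
decline classes, and the top-risk units holding 20% of the population.
"""

import pandas as pd
from common import make_run, publish

from diarmap.pipeline import stage_aggregate

run = make_run(__doc__)
world, aggs, change = stage_aggregate(run)

gini = pd.read_csv(run.path("gini.csv"))
mort = gini[gini["measure"] == "mortality"]
print("mortality Gini across admin2 units:",
      {int(r.year): round(r.gini, 3) for r in mort.itertuples()})
dev = pd.read_csv(run.path("deviations.csv"))
worst = dev[dev["measure"] == "mortality"].nlargest(1, "relative_mean_pct")
if len(worst):
    r = worst.iloc[0]
    print(f"largest relative mortality deviation: unit {r.unit_id} in "
          f"{int(r.year)}, {r.relative_mean_pct:.1f}% above its country mean")
print(f"share of units with mortality declining >10%/year: "
      f"{change.share_declining_mean:.1%} "
      f"(95% UI {change.share_declining_lower:.1%}-"
      f"{change.share_declining_upper:.1%})")
top = pd.read_csv(run.path("top_risk_units.csv"))
print(f"top-risk units holding 20% of population: {len(top)} "
      f"({', '.join(top['unit_id'].head(5))}...)")
publish(run, "admin2_estimates.csv", "admin1_estimates.csv",
        "country_estimates.csv", "deviations.csv", "gini.csv",
        "change_classes.csv", "top_risk_units.csv")
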