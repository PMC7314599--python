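"""Admin-unit aggregation, uncertainty intervals, and inequality metrics.

Draw cubes aggregate to admin units as population-weighted means, draw by
draw, so every downstream statement — uncertainty intervals (2.5th/97.5th
percentiles across draws), unit-vs-country deviations, Gini coefficients,
decline classification — can be made on the joint posterior rather than on
point estimates.  Percentiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geomodel import PrevalenceDraws
from .worldgen import AdminHierarchy

__all__ = [
    "AggregatedEstimates",
    "aggregate",
    "deviations",
    "gini",
    "classify_change",
    "ChangeResult",
    "top_risk_units",
]


@dataclass
class AggregatedEstimates:
    """Population-weighted unit-level draws plus their summary.

    ``values`` has shape (nunits, nyears, ndraws) and holds rates; units with
    zero population carry NaN rates and zero counts.
    """

    unit_ids: list[str]
    level: int
    years: tuple[int, ...]
    measure: str
    values: np.ndarray
    population: np.ndarray  # (nunits, nyears)

    def unit_index(self, unit_id: str) -> int:
        return self.unit_ids.index(unit_id)

    def year_index(self, year: int) -> int:
        return self.years.index(year)

    def counts(self) -> np.ndarray:
        """Per-draw counts: rate x under-5 population."""
        vals = np.where(np.isnan(self.values), 0.0, self.values)
        return vals * self.population[:, :, None]

    def summary(self) -> pd.DataFrame:
        counts = self.counts()
        rows = []
        for i, uid in enumerate(self.unit_ids):
            for t, year in enumerate(self.years):
                v = self.values[i, t, :]
                c = counts[i, t, :]
                if np.isnan(v).all():
                    mean = lo = hi = np.nan
                else:
                    mean = float(v.mean())
                    lo, hi = np.percentile(v, [2.5, 97.5])
                rows.append({
                    "unit_id": uid,
                    "level": self.level,
                    "year": year,
                    "measure": self.measure,
                    "mean": mean,
                    "lower": float(lo),
                    "upper": float(hi),
                    "count_mean": float(c.mean()),
                    "count_lower": float(np.percentile(c, 2.5)),
                    "count_upper": float(np.percentile(c, 97.5)),
                    "population": float(self.population[i, t]),
                })
        return pd.DataFrame(rows)


def aggregate(
    draws: PrevalenceDraws,
    population: np.ndarray,
    hierarchy: AdminHierarchy,
    level: int,
) -> AggregatedEstimates:
    """Population-weighted aggregation of draws to admin units at ``level``."""
    ncells, nyears, ndraws = draws.values.shape
    if population.shape != (ncells, nyears):
        raise ValueError(
            f"population shape {population.shape} does not match draw grid "
            f"({ncells}, {nyears})"
        )
    if len(hierarchy.cell_admin2) != ncells:
        raise ValueError("hierarchy does not cover the draw grid")
    membership = hierarchy.cell_membership(level)
    unit_ids = sorted(membership)
    values = np.full((len(unit_ids), nyears, ndraws), np.nan)
    pops = np.zeros((len(unit_ids), nyears))
    for i, uid in enumerate(unit_ids):
        cells = membership[uid]
        if len(cells) == 0:
            continue
        pop = population[cells, :]  # (nc, nyears)
        pops[i] = pop.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            num = np.einsum("ct,ctk->tk", pop, draws.values[cells, :, :])
            values[i] = num / pops[i][:, None]
        values[i][pops[i] == 0, :] = np.nan  # zero-population: rate undefined
    return AggregatedEstimates(
        unit_ids=unit_ids,
        level=level,
        years=draws.years,
        measure=draws.measure,
        values=values,
        population=pops,
    )


def deviations(
    agg_country: AggregatedEstimates,
    agg_units: AggregatedEstimates,
    hierarchy: AdminHierarchy,
) -> pd.DataFrame:
    """Unit-vs-country deviations, per draw, summarised by mean and 95% UI.

    Three forms per unit-year: absolute (unit - country, rate units), ratio
    (unit / country), and relative ((unit / country) - 1, in percent).  The
    per-draw minimum ratio is retained so statements like "at least X% higher
    in every draw" are reproducible.  A country rate of zero leaves the ratio
    forms missing while the absolute deviation is still computed.
    """
    cidx = {uid: i for i, uid in enumerate(agg_country.unit_ids)}
    rows = []
    for i, uid in enumerate(agg_units.unit_ids):
        country = hierarchy.country_of(uid)
        ci = cidx[country]
        for t, year in enumerate(agg_units.years):
            u = agg_units.values[i, t, :]
            c = agg_country.values[ci, t, :]
            absolute = u - c
            row = {
                "unit_id": uid,
                "country": country,
                "year": year,
                "measure": agg_units.measure,
                "absolute_mean": float(np.nanmean(absolute)),
                "absolute_lower": float(np.nanpercentile(absolute, 2.5)),
                "absolute_upper": float(np.nanpercentile(absolute, 97.5)),
            }
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(c > 0, u / c, np.nan)
            if np.isnan(ratio).all():
                row.update(ratio_mean=np.nan, relative_mean_pct=np.nan,
                           ratio_lower=np.nan, ratio_upper=np.nan,
                           ratio_min=np.nan)
            else:
                row.update(
                    ratio_mean=float(np.nanmean(ratio)),
                    ratio_lower=float(np.nanpercentile(ratio, 2.5)),
                    ratio_upper=float(np.nanpercentile(ratio, 97.5)),
                    ratio_min=float(np.nanmin(ratio)),
                    relative_mean_pct=float((np.nanmean(ratio) - 1.0) * 100.0),
                )
            rows.append(row)
    return pd.DataFrame(rows)


def gini(rates: np.ndarray, populations: np.ndarray) -> float:
    """Population-weighted Gini coefficient across units.

    G = sum_i sum_j w_i w_j |x_i - x_j| / (2 mu) with w the normalised
    population shares and mu the weighted mean rate; 0 is perfect equality,
    1 maximal inequality.  A zero mean returns 0 by convention.  Computed in
    O(n log n) via sorting; an O(n^2) double loop gives the same value.
    """
    rates = np.asarray(rates, dtype=float)
    populations = np.asarray(populations, dtype=float)
    if rates.shape != populations.shape:
        raise ValueError("rates and populations must have matching shapes")
    keep = populations > 0
    if not keep.any():
        raise ValueError("need at least one unit with positive population")
    x = rates[keep]
    if (x < 0).any():
        raise ValueError("rates must be non-negative")
    w = populations[keep] / populations[keep].sum()
    mu = float(np.sum(w * x))
    if mu == 0.0:
        return 0.0
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cxw = np.cumsum(x * w)
    # sum_{i<j} w_i w_j (x_j - x_i), doubled, over 2 mu
    pair = np.sum(w * (x * np.concatenate([[0.0], cw[:-1]])
                       - np.concatenate([[0.0], cxw[:-1]])))
    return float(2.0 * pair / (2.0 * mu))


@dataclass
class ChangeResult:
    units: pd.DataFrame  # unit_id, mean_change, declined (bool), n_excluded_draws
    share_declining_mean: float
    share_declining_lower: float
    share_declining_upper: float
    mode: str
    threshold: float


def classify_change(
    agg: AggregatedEstimates,
    year0: int,
    year1: int,
    threshold: float = 0.10,
    mode: str = "annualised",
) -> ChangeResult:
    """Classify units by decline between two years, with draw-based UI.

    ``annualised`` change is (x1/x0)^(1/(y1-y0)) - 1 per draw; ``total`` is
    x1/x0 - 1.  A unit is declining when its change is <= -threshold.  The
    share of declining units is computed within each draw and summarised by
    its mean and 2.5/97.5 percentiles.  Unit-draws with x0 = 0 are excluded
    (with a count kept per unit).
    """
    if mode not in ("annualised", "total"):
        raise ValueError(f"unknown change mode {mode!r}")
    t0, t1 = agg.year_index(year0), agg.year_index(year1)
    span = year1 - year0
    x0 = agg.values[:, t0, :]
    x1 = agg.values[:, t1, :]
    valid = (x0 > 0) & ~np.isnan(x1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, x1 / x0, np.nan)
        change = ratio ** (1.0 / span) - 1.0 if mode == "annualised" else ratio - 1.0
    declined = change <= -threshold  # (nunits, ndraws), NaN-> False
    rows = []
    for i, uid in enumerate(agg.unit_ids):
        ch = change[i, valid[i]]
        rows.append({
            "unit_id": uid,
            "mean_change": float(ch.mean()) if ch.size else np.nan,
            "declined": bool(ch.size and ch.mean() <= -threshold),
            "n_excluded_draws": int((~valid[i]).sum()),
        })
    with np.errstate(invalid="ignore"):
        share = np.nansum(declined & valid, axis=0) / np.maximum(
            valid.sum(axis=0), 1
        )
    return ChangeResult(
        units=pd.DataFrame(rows),
        share_declining_mean=float(share.mean()),
        share_declining_lower=float(np.percentile(share, 2.5)),
        share_declining_upper=float(np.percentile(share, 97.5)),
        mode=mode,
        threshold=threshold,
    )


def top_risk_units(
    summary: pd.DataFrame, fraction: float = 0.20
) -> list[str]:
    """Units covering the top ``fraction`` of population by mortality rate.

    ``summary`` needs columns unit_id, mean, population (one row per unit for
    a single year/measure).  Units are sorted by mean rate descending (ties:
    larger population first, then unit id) and taken until the cumulative
    population share first reaches ``fraction``; the boundary unit is
    included.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    df = summary[summary["population"] > 0]
    total = df["population"].sum()
    if total <= 0:
        raise ValueError("zero total population")
    df = df.sort_values(
        by=["mean", "population", "unit_id"], ascending=[False, False, True]
    )
    chosen = []
    acc = 0.0
    for _, row in df.iterrows():
        chosen.append(row["unit_id"])
        acc += row["population"] / total
        if acc >= fraction - 1e-12:
            break
    return chosen
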