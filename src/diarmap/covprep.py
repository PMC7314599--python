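"""Covariate preparation: collinearity filtering and polygon resampling.

Variance inflation factors (VIF) flag multicollinear covariates before they
enter the learners; covariates are dropped greedily (largest VIF first, ties
broken alphabetically) until every retained covariate has VIF at or below the
threshold (default 3).  Polygon survey records — observations tied to an admin
unit rather than a cluster coordinate — are resampled into point pseudo-clusters
at population-weighted cells so that the geostatistical model only ever sees
point data, with child and case totals conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .worldgen import SURVEY_COLUMNS, World

__all__ = [
    "VifReport",
    "compute_vif",
    "vif_filter",
    "vif_filter_by_region",
    "resample_polygons",
    "ResamplingError",
]


class ResamplingError(ValueError):
    """Polygon resampling failed for a named unit."""


@dataclass
class VifReport:
    vif: dict[str, float]  # per-covariate VIF at termination
    retained: list[str]
    dropped: list[str]  # in drop order
    threshold: float


def _vif_values(x: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j), R^2_j from regressing column j on the rest.

    Regressions include an intercept.  A column that is constant across rows
    (or otherwise perfectly explained) gets an infinite VIF.
    """
    n, p = x.shape
    if p < 2:
        raise ValueError("VIF needs at least two covariate columns")
    if n < p + 1:
        raise ValueError(f"VIF rank error: {n} rows for {p} columns (need >= {p + 1})")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate matrix contains non-finite entries")
    out = np.empty(p)
    for j in range(p):
        y = x[:, j]
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0.0:  # constant column
            out[j] = np.inf
            continue
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        rss = np.sum((y - others @ coef) ** 2)
        r2 = 1.0 - rss / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def compute_vif(covariates: pd.DataFrame) -> dict[str, float]:
    """Per-column variance inflation factors of a covariate table."""
    vals = _vif_values(covariates.to_numpy(dtype=float))
    return dict(zip(covariates.columns, (float(v) for v in vals)))


def vif_filter(covariates: pd.DataFrame, threshold: float = 3.0) -> VifReport:
    """Greedily drop the largest-VIF covariate until all VIF <= threshold.

    Ties on the maximum VIF are broken by alphabetical column name (the
    alphabetically first of the tied columns is dropped), so the procedure is
    reproducible.  At least one covariate is always retained.
    """
    if covariates.shape[1] == 0:
        raise ValueError("empty covariate matrix")
    current = list(covariates.columns)
    dropped: list[str] = []
    while len(current) > 1:
        vifs = compute_vif(covariates[current])
        vmax = max(vifs.values())
        if vmax <= threshold:
            break
        worst = sorted(name for name, v in vifs.items() if v == vmax)[0]
        dropped.append(worst)
        current.remove(worst)
    final = (
        compute_vif(covariates[current])
        if len(current) > 1
        else {current[0]: 1.0}
    )
    return VifReport(vif=final, retained=current, dropped=dropped, threshold=threshold)


def vif_filter_by_region(
    covariates: pd.DataFrame,
    regions: np.ndarray,
    threshold: float = 3.0,
) -> dict[str, VifReport]:
    """Run the VIF filter independently within each modelling region.

    ``regions`` assigns each row of ``covariates`` to a region (e.g. the
    country of its cell); each region gets its own retained set.  The
    single-region :func:`vif_filter` is the default at desk scale.
    """
    out = {}
    for region in pd.unique(regions):
        out[region] = vif_filter(covariates[regions == region],
                                 threshold=threshold)
    return out


def largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Split a non-negative integer ``total`` by ``shares`` (sum 1) exactly.

    Floors the ideal allocations and hands the remaining units to the largest
    fractional remainders; ties go to the lower index.  The result sums to
    ``total`` exactly.
    """
    ideal = total * shares
    base = np.floor(ideal).astype(int)
    short = int(total - base.sum())
    if short > 0:
        remainders = ideal - base
        order = np.lexsort((np.arange(len(shares)), -remainders))
        base[order[:short]] += 1
    return base


def resample_polygons(
    records: pd.DataFrame, world: World, k: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Expand polygon records into point pseudo-clusters.

    Each polygon record becomes ``min(k, cells-in-unit)`` point records at
    cells drawn without replacement with probability proportional to the
    unit's population in the record's year.  ``n_children`` is split across
    the sampled cells proportionally to their population shares by the
    largest-remainder rule, and ``n_cases`` by the same shares (capped at the
    children allocated to a cell); both totals are conserved exactly.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    rng = np.random.default_rng(seed)
    membership = world.admin.cell_membership(2)
    membership.update(world.admin.cell_membership(1))
    membership.update(world.admin.cell_membership(0))

    out_rows = []
    for idx, rec in records.iterrows():
        if rec["geometry_kind"] != "polygon":
            out_rows.append(rec[SURVEY_COLUMNS].to_dict())
            continue
        uid = rec["admin_unit_id"]
        if uid not in membership:
            raise ResamplingError(f"polygon record references unknown unit {uid!r}")
        cells = membership[uid]
        t = world.year_index(int(rec["year"]))
        pop = world.population[cells, t]
        total_pop = pop.sum()
        if total_pop <= 0:
            raise ResamplingError(f"unit {uid!r} has zero population; cannot resample")
        positive = cells[pop > 0]
        m = min(k, len(positive))
        probs = world.population[positive, t] / world.population[positive, t].sum()
        chosen = rng.choice(positive, size=m, replace=False, p=probs)
        shares = world.population[chosen, t]
        shares = shares / shares.sum()
        children = largest_remainder(int(rec["n_children"]), shares)
        cases = largest_remainder(int(rec["n_cases"]), shares)
        cases = _cap_cases(cases, children)
        for cell, n_i, y_i in zip(chosen, children, cases):
            r, c = world.grid.rowcol(int(cell))
            if n_i == 0:
                continue
            out_rows.append(
                {
                    "source_id": rec["source_id"],
                    "year": int(rec["year"]),
                    "geometry_kind": "point",
                    "cell_row": int(r),
                    "cell_col": int(c),
                    "admin_unit_id": world.admin.cell_admin2[int(cell)],
                    "n_children": int(n_i),
                    "n_cases": int(y_i),
                    "weight": float(rec["weight"]),
                }
            )
    return pd.DataFrame(out_rows, columns=SURVEY_COLUMNS)


def _cap_cases(cases: np.ndarray, children: np.ndarray) -> np.ndarray:
    """Ensure cases_i <= children_i cellwise while conserving the case total."""
    cases = cases.copy()
    excess = cases - children
    overflow = int(excess[excess > 0].sum())
    cases = np.minimum(cases, children)
    while overflow > 0:
        room = children - cases
        j = int(np.argmax(room))
        if room[j] <= 0:  # pragma: no cover - cannot happen when total cases <= total children
            break
        move = min(overflow, int(room[j]))
        cases[j] += move
        overflow -= move
    return cases
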