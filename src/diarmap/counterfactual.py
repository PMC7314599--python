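"""Risk-factor counterfactuals: averted deaths and attributable fractions.

For a dichotomous risk factor with risk ratio RR and exposed proportion x, the
population-average relative risk is s(x) = 1 + x (RR - 1).  Under the
assumption that each risk factor acts on diarrhoeal mortality independently and
changes through time independently of the others, the counterfactual death
count with exposures returned to a reference year is

    D_cf = D_obs * prod_r s_r(x_r,ref) / s_r(x_r,obs),

and the population attributable fraction of the current exposures is
PAF = 1 - 1 / prod_r s_r(x_r).  WASH (prevent) and CGF (protect) groups are
reported separately and combined; the treat group (ORS) is excluded from the
default counterfactual because its risk ratio acts on case fatality rather
than incidence, and is only included behind an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .worldgen import AdminHierarchy, RiskFactor

__all__ = [
    "CounterfactualResult",
    "exposure_scalar",
    "averted_deaths",
    "attributable_fraction",
    "dominant_driver",
    "GROUP_LABELS",
]

# GAPPD-style grouping: prevent = WASH, protect = CGF, treat = ORS
GROUP_LABELS = {"prevent": "WASH", "protect": "CGF", "treat": "ORS"}


def exposure_scalar(x, rr: float):
    """Population-average relative risk s = 1 + x (rr - 1) for exposure x."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("exposure must lie in [0, 1]")
    if not np.isfinite(rr) or rr <= 0:
        raise ValueError(f"risk ratio must be finite and positive, got {rr}")
    s = 1.0 + x * (rr - 1.0)
    return float(s) if s.ndim == 0 else s


def _group_ratio(
    factors: Sequence[RiskFactor],
    t_ref: int,
    t_obs: int,
    groups: Iterable[str],
) -> np.ndarray:
    """prod_r s_r(x_ref)/s_r(x_obs) per cell over the named risk groups."""
    ratio = None
    for rf in factors:
        if rf.group not in groups:
            continue
        s_ref = exposure_scalar(rf.exposure[:, t_ref], rf.rr)
        s_obs = exposure_scalar(rf.exposure[:, t_obs], rf.rr)
        term = s_ref / s_obs
        ratio = term if ratio is None else ratio * term
    if ratio is None:
        raise ValueError(f"no risk factors in groups {sorted(groups)}")
    return ratio


@dataclass
class CounterfactualResult:
    """Per-unit counterfactual summary for the observation year.

    ``units`` columns: unit_id, observed/counterfactual/averted death counts
    (mean, lower, upper across draws), averted_per_1000 (rate per 1000
    children), wash_averted_mean, cgf_averted_mean, dominant driver label,
    attributable fraction (mean).  ``totals`` holds the same aggregated over
    all units per draw (mean/lower/upper).
    """

    units: pd.DataFrame
    totals: dict[str, float]
    year_ref: int
    year_obs: int


def averted_deaths(
    mortality_draws: np.ndarray,
    population: np.ndarray,
    factors: Sequence[RiskFactor],
    hierarchy: AdminHierarchy,
    t_ref: int,
    t_obs: int,
    year_ref: int,
    year_obs: int,
    level: int = 2,
    include_treat: bool = False,
    dominance_share: float = 0.5,
) -> CounterfactualResult:
    """Deaths averted in the observation year by exposure changes since ref.

    ``mortality_draws`` is the (ncells, ndraws) mortality-rate slice for the
    observation year; ``population`` the matching (ncells,) under-5 counts.
    Population and mortality stay fixed at their observed-year levels — only
    risk-factor exposures are rolled back, per the independence assumption.
    """
    groups_wash = {"prevent"}
    groups_cgf = {"protect"}
    groups_all = {"prevent", "protect"} | ({"treat"} if include_treat else set())

    ratio_all = _group_ratio(factors, t_ref, t_obs, groups_all)
    ratio_wash = _group_ratio(factors, t_ref, t_obs, groups_wash)
    ratio_cgf = _group_ratio(factors, t_ref, t_obs, groups_cgf)

    d_obs = mortality_draws * population[:, None]  # (ncells, ndraws)
    paf_cell = attributable_fraction(
        {rf.name: rf.exposure[:, t_obs] for rf in factors},
        [rf for rf in factors if rf.group in groups_all],
    )

    membership = hierarchy.cell_membership(level)
    rows = []
    tot_avert = None
    for uid in sorted(membership):
        cells = membership[uid]
        if len(cells) == 0:
            continue
        obs = d_obs[cells, :].sum(axis=0)
        cf = (d_obs[cells, :] * ratio_all[cells, None]).sum(axis=0)
        avert = cf - obs
        wash = (d_obs[cells, :] * (ratio_wash[cells, None] - 1.0)).sum(axis=0)
        cgf = (d_obs[cells, :] * (ratio_cgf[cells, None] - 1.0)).sum(axis=0)
        pop_u = population[cells].sum()
        label = dominant_driver(
            float(wash.mean()), float(cgf.mean()), float(avert.mean()),
            dominance_share=dominance_share,
        )
        pw = d_obs[cells, :].mean(axis=1).sum()
        paf_u = (
            float((paf_cell[cells] * d_obs[cells, :].mean(axis=1)).sum() / pw)
            if pw > 0
            else float(paf_cell[cells].mean())
        )
        rows.append({
            "unit_id": uid,
            "observed_mean": float(obs.mean()),
            "counterfactual_mean": float(cf.mean()),
            "averted_mean": float(avert.mean()),
            "averted_lower": float(np.percentile(avert, 2.5)),
            "averted_upper": float(np.percentile(avert, 97.5)),
            "averted_per_1000": float(avert.mean() / pop_u * 1000.0) if pop_u else np.nan,
            "wash_averted_mean": float(wash.mean()),
            "cgf_averted_mean": float(cgf.mean()),
            "dominant_driver": label,
            "attributable_fraction": paf_u,
            "population": float(pop_u),
        })
        tot_avert = avert if tot_avert is None else tot_avert + avert
    totals = {
        "averted_mean": float(tot_avert.mean()),
        "averted_lower": float(np.percentile(tot_avert, 2.5)),
        "averted_upper": float(np.percentile(tot_avert, 97.5)),
    }
    return CounterfactualResult(
        units=pd.DataFrame(rows), totals=totals,
        year_ref=year_ref, year_obs=year_obs,
    )


def attributable_fraction(
    exposures: dict[str, np.ndarray],
    factors: Sequence[RiskFactor],
) -> np.ndarray:
    """PAF = 1 - 1 / prod_r s_r(x_r), elementwise over cells.

    ``exposures`` maps factor name to the exposure array to evaluate (so the
    same factors can be scored at different years).  A factor supplied with
    rr < 1 is protective at the "harmful" coding and triggers a warning since
    the PAF may then be negative.
    """
    import warnings

    prod = None
    for rf in factors:
        x = exposures[rf.name]
        if rf.rr < 1.0:
            warnings.warn(
                f"risk factor {rf.name!r} has rr < 1 (protective); "
                "attributable fraction may be negative",
                stacklevel=2,
            )
        s = exposure_scalar(x, rf.rr)
        prod = s if prod is None else prod * s
    if prod is None:
        raise ValueError("no risk factors supplied")
    return 1.0 - 1.0 / prod


def dominant_driver(
    wash_averted: float,
    cgf_averted: float,
    combined_averted: float,
    dominance_share: float = 0.5,
) -> str:
    """Label the group contributing most of the reduction: WASH, CGF or none.

    A group is dominant when its single-group averted deaths exceed
    ``dominance_share`` of the combined total; ties, non-positive combined
    totals, and cases where neither group exceeds the share give "none".
    """
    if combined_averted <= 0:
        return "none"
    wash_dom = wash_averted > dominance_share * combined_averted
    cgf_dom = cgf_averted > dominance_share * combined_averted
    if wash_dom and cgf_dom:
        # both can exceed 0.5 only through negative interaction; larger wins
        if wash_averted == cgf_averted:
            return "none"
        return "WASH" if wash_averted > cgf_averted else "CGF"
    if wash_dom:
        return "WASH"
    if cgf_dom:
        return "CGF"
    return "none"
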