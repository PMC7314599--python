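"""Prevalence -> incidence -> mortality conversion and raking to envelopes.

Point prevalence converts to incidence (episodes per child-year) through the
mean episode duration d: incidence = prevalence * 365 / d, with d = 4.2 days by
default.  Incidence converts to mortality through country-year case-fatality
rates that do not vary subnationally.  Each measure's draws are then *raked*:
for every draw and country-year, a calibration factor is chosen so that the
population-weighted national aggregate equals the national envelope.  Rates
(incidence, mortality) are raked multiplicatively with a closed-form factor;
prevalence is raked by a logit shift (solved by a monotone 1-D root find) so
raked values stay inside [0, 1].  Raking per draw, rather than on the mean,
keeps the uncertainty intervals honest after calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .geomodel import PrevalenceDraws
from .worldgen import DAYS_PER_YEAR, NationalInputs, World

__all__ = [
    "EPISODE_DURATION_DAYS",
    "RakingError",
    "RakingFactors",
    "prevalence_to_incidence",
    "incidence_to_prevalence",
    "apply_cfr",
    "rake",
]

EPISODE_DURATION_DAYS = 4.2  # mean duration of a diarrhoea episode


class RakingError(RuntimeError):
    pass


@dataclass
class RakingFactors:
    """Per (country, year, draw) calibration factors.

    ``table`` columns: country, year, draw, factor.  For multiplicative raking
    the factor multiplies the surface; for logit raking it is the additive
    shift delta on the logit scale.
    """

    table: pd.DataFrame
    mode: str
    measure: str


def prevalence_to_incidence(
    draws: PrevalenceDraws, duration: float = EPISODE_DURATION_DAYS
) -> PrevalenceDraws:
    """Episodes per child-year from point prevalence, elementwise per draw."""
    if duration <= 0:
        raise ValueError(f"episode duration must be positive, got {duration}")
    return replace(
        draws, values=draws.values * (DAYS_PER_YEAR / duration), measure="incidence"
    )


def incidence_to_prevalence(
    draws: PrevalenceDraws, duration: float = EPISODE_DURATION_DAYS
) -> PrevalenceDraws:
    """Inverse of :func:`prevalence_to_incidence` (exact round trip)."""
    if duration <= 0:
        raise ValueError(f"episode duration must be positive, got {duration}")
    return replace(
        draws, values=draws.values / (DAYS_PER_YEAR / duration), measure="prevalence"
    )


def apply_cfr(
    incidence: PrevalenceDraws,
    national_inputs: NationalInputs,
    cell_country: np.ndarray,
) -> PrevalenceDraws:
    """Mortality (deaths per child-year) = incidence x country-year CFR.

    The CFR is shared by every cell of a country in a given year; a missing
    (country, year) entry raises a KeyError naming the pair.
    """
    ncells, nyears, _ = incidence.values.shape
    cfr = np.empty((ncells, nyears))
    countries = pd.unique(cell_country)
    for country in countries:
        mask = cell_country == country
        for t, year in enumerate(incidence.years):
            cfr[mask, t] = national_inputs.cfr(country, year)
    return replace(incidence, values=incidence.values * cfr[:, :, None],
                   measure="mortality")


def _solve_logit_shift(p, pop, target, tol=1e-10):
    """Monotone root find for delta: sum pop*expit(logit(p)+delta) / sum pop = target."""
    lp = logit(np.clip(p, 1e-12, 1 - 1e-12))
    wsum = pop.sum()

    def gap(delta):
        return float((pop * expit(lp + delta)).sum() / wsum - target)

    lo, hi = -1.0, 1.0
    for _ in range(60):
        if gap(lo) < 0:
            break
        lo *= 2
    for _ in range(60):
        if gap(hi) > 0:
            break
        hi *= 2
    return brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16)


def rake(
    draws: PrevalenceDraws,
    population: np.ndarray,
    envelopes: pd.Series,
    cell_country: np.ndarray,
    mode: str = "multiplicative",
    exclude: set[str] | frozenset[str] = frozenset(),
) -> tuple[PrevalenceDraws, RakingFactors]:
    """Calibrate every draw's national aggregates to the envelopes.

    Parameters
    ----------
    draws : the measure's joint posterior draws (ncells, nyears, ndraws).
    population : (ncells, nyears) under-5 population used as weights.
    envelopes : Series indexed by (country, year) with the national target.
    cell_country : per-cell country id.
    mode : ``multiplicative`` (closed-form factor) or ``logit`` (bounded
        measures; additive shift on the logit scale found by root-finding).
    exclude : countries left uncalibrated (factor 1 / shift 0), mirroring
        national envelopes judged unusable for a location.
    """
    if mode not in ("multiplicative", "logit"):
        raise ValueError(f"unknown raking mode {mode!r}")
    values = draws.values.copy()
    ncells, nyears, ndraws = values.shape
    rows = []
    for country in pd.unique(cell_country):
        mask = cell_country == country
        for t, year in enumerate(draws.years):
            pop = population[mask, t]
            wsum = pop.sum()
            if country in exclude:
                for k in range(ndraws):
                    rows.append((country, year, k, 1.0 if mode == "multiplicative" else 0.0))
                continue
            try:
                target = float(envelopes.loc[(country, year)])
            except KeyError:
                raise RakingError(f"no envelope for ({country}, {year})")
            for k in range(ndraws):
                v = values[mask, t, k]
                agg = float((v * pop).sum() / wsum) if wsum > 0 else 0.0
                if mode == "multiplicative":
                    if agg == 0.0:
                        if target != 0.0:
                            raise RakingError(
                                f"zero national aggregate with nonzero envelope "
                                f"for ({country}, {year}, draw {k})"
                            )
                        factor = 1.0
                    else:
                        factor = target / agg
                    values[mask, t, k] = v * factor
                    rows.append((country, year, k, factor))
                else:
                    if agg == 0.0 and target != 0.0:
                        raise RakingError(
                            f"zero national aggregate with nonzero envelope "
                            f"for ({country}, {year}, draw {k})"
                        )
                    delta = _solve_logit_shift(v, pop, target) if agg != target else 0.0
                    values[mask, t, k] = expit(
                        logit(np.clip(v, 1e-12, 1 - 1e-12)) + delta
                    )
                    rows.append((country, year, k, delta))
    factors = RakingFactors(
        table=pd.DataFrame(rows, columns=["country", "year", "draw", "factor"]),
        mode=mode,
        measure=draws.measure,
    )
    return replace(draws, values=values), factors
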