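"""Seeded generator of synthetic survey worlds.

A *world* bundles everything the burden pipeline consumes: a regular lat/lon
grid, a three-level admin hierarchy (country -> admin1 -> admin2) whose units
are contiguous rectangular cell blocks, a heavy-tailed under-5 population
surface, and a stack of standardized covariates.  On top of a world the module
simulates a known truth prevalence surface (logit-linear fixed effects plus a
separable Matern x AR1 space-time GP plus an iid nugget), DHS-like cluster and
polygon surveys with binomial outcomes, national envelope/case-fatality tables,
and risk-factor exposure surfaces.  Everything is deterministic for a fixed
(config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .gp import grid_coords, sample_separable_field

__all__ = [
    "Grid",
    "AdminHierarchy",
    "World",
    "WorldConfig",
    "TruthParams",
    "GPParams",
    "TruthSurface",
    "SurveyDesign",
    "NationalParams",
    "RiskFactorSpec",
    "NationalInputs",
    "RiskFactor",
    "ConfigurationError",
    "generate_world",
    "simulate_truth",
    "simulate_surveys",
    "simulate_national_inputs",
    "SURVEY_COLUMNS",
    "validate_surveys",
]

DAYS_PER_YEAR = 365.0

SURVEY_COLUMNS = [
    "source_id",
    "year",
    "geometry_kind",
    "cell_row",
    "cell_col",
    "admin_unit_id",
    "n_children",
    "n_cases",
    "weight",
]


class ConfigurationError(ValueError):
    """A world/survey configuration that cannot be realised."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid:
    """Regular raster grid; cells are indexed row-major from the NW corner."""

    nrows: int
    ncols: int
    cell_deg: float = 0.1
    origin_lon: float = 0.0
    origin_lat: float = 0.0

    def __post_init__(self):
        if self.nrows < 1 or self.ncols < 1:
            raise ConfigurationError("grid must have positive dimensions")

    @property
    def ncells(self) -> int:
        return self.nrows * self.ncols

    def cell_index(self, row: int, col: int) -> int:
        return row * self.ncols + col

    def rowcol(self, cell: np.ndarray | int):
        return np.divmod(cell, self.ncols)

    def coords(self) -> np.ndarray:
        """Cell centroids in cell units (row, col), row-major."""
        return grid_coords(self.nrows, self.ncols)


@dataclass
class AdminHierarchy:
    """country -> admin1 -> admin2 tree plus per-cell admin2 ownership.

    ``units`` columns: unit_id, level (0/1/2), parent_id (empty for level 0),
    country_id.  ``cell_admin2`` maps each grid cell to its admin2 unit_id.
    """

    units: pd.DataFrame
    cell_admin2: np.ndarray  # (ncells,) of admin2 unit_id strings

    def __post_init__(self):
        self._by_id = self.units.set_index("unit_id")
        admin2 = set(self.units_at_level(2))
        owners = set(np.unique(self.cell_admin2))
        if not owners <= admin2:
            raise ConfigurationError(
                f"cells owned by unknown admin2 units: {sorted(owners - admin2)}"
            )

    def units_at_level(self, level: int) -> list[str]:
        return self.units.loc[self.units["level"] == level, "unit_id"].tolist()

    def parent(self, unit_id: str) -> str:
        return self._by_id.at[unit_id, "parent_id"]

    def level(self, unit_id: str) -> int:
        return int(self._by_id.at[unit_id, "level"])

    def country_of(self, unit_id: str) -> str:
        return self._by_id.at[unit_id, "country_id"]

    def cell_membership(self, level: int) -> dict[str, np.ndarray]:
        """unit_id -> array of cell indices, for any hierarchy level."""
        admin2_cells: dict[str, np.ndarray] = {}
        for uid in self.units_at_level(2):
            admin2_cells[uid] = np.flatnonzero(self.cell_admin2 == uid)
        if level == 2:
            return admin2_cells
        out: dict[str, list[np.ndarray]] = {u: [] for u in self.units_at_level(level)}
        for uid, cells in admin2_cells.items():
            anc = uid
            while self.level(anc) != level:
                anc = self.parent(anc)
            out[anc].append(cells)
        return {
            u: (np.concatenate(parts) if parts else np.empty(0, dtype=int))
            for u, parts in out.items()
        }

    def cell_country(self) -> np.ndarray:
        """Per-cell country_id, aligned with ``cell_admin2``."""
        lut = self._by_id["country_id"]
        return lut.loc[self.cell_admin2].to_numpy()


@dataclass(frozen=True)
class Standardization:
    mean: float
    sd: float


@dataclass
class World:
    grid: Grid
    years: tuple[int, ...]
    admin: AdminHierarchy
    population: np.ndarray  # (ncells, nyears), >= 0
    covariates: dict[str, np.ndarray]  # name -> (ncells, nyears), standardized
    covariate_standardization: dict[str, Standardization]
    covariate_static: dict[str, bool]

    @property
    def nyears(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise KeyError(f"year {year} not in world ({self.years[0]}..{self.years[-1]})")

    def covariate_matrix(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stack covariates into an array (ncells, nyears, ncov)."""
        names = list(names) if names is not None else sorted(self.covariates)
        return np.stack([self.covariates[n] for n in names], axis=-1)


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldConfig:
    nrows: int = 20
    ncols: int = 20
    cell_deg: float = 0.1
    years: tuple[int, ...] = tuple(range(2000, 2018))
    n_countries: int = 3
    n_admin1_per_country: int = 2
    n_admin2_per_admin1: int = 2
    n_covariates: int = 8
    n_collinear: int = 2
    time_varying_fraction: float = 0.5
    covariate_range: float = 6.0  # cells
    pop_log_mean: float = np.log(200.0)
    pop_log_sd: float = 1.5  # heavy-tailed: a few cells dominate
    pop_growth: float = 0.015  # deterministic annual growth

    def __post_init__(self):
        for name in ("n_countries", "n_admin1_per_country", "n_admin2_per_admin1"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_covariates < 1:
            raise ConfigurationError("need at least one covariate")
        if len(self.years) < 1:
            raise ConfigurationError("need at least one year")


def _split_blocks(n_items: int, n_parts: int) -> list[np.ndarray]:
    if n_parts > n_items:
        raise ConfigurationError(
            f"cannot split {n_items} cells into {n_parts} contiguous blocks"
        )
    return np.array_split(np.arange(n_items), n_parts)


def _build_hierarchy(config: WorldConfig, grid: Grid) -> AdminHierarchy:
    rows_by_country = _split_blocks(grid.nrows, config.n_countries)
    units: list[dict] = []
    cell_admin2 = np.empty(grid.ncells, dtype=object)
    for ci, country_rows in enumerate(rows_by_country):
        cid = f"C{ci:02d}"
        units.append({"unit_id": cid, "level": 0, "parent_id": "", "country_id": cid})
        cols_by_a1 = _split_blocks(grid.ncols, config.n_admin1_per_country)
        for ai, a1_cols in enumerate(cols_by_a1):
            a1id = f"{cid}.A{ai:02d}"
            units.append(
                {"unit_id": a1id, "level": 1, "parent_id": cid, "country_id": cid}
            )
            rows_by_a2 = np.array_split(country_rows, config.n_admin2_per_admin1)
            if any(len(r) == 0 for r in rows_by_a2):
                raise ConfigurationError(
                    f"country {cid} has too few rows for "
                    f"{config.n_admin2_per_admin1} admin2 bands"
                )
            for di, a2_rows in enumerate(rows_by_a2):
                a2id = f"{a1id}.D{di:02d}"
                units.append(
                    {"unit_id": a2id, "level": 2, "parent_id": a1id, "country_id": cid}
                )
                for r in a2_rows:
                    for c in a1_cols:
                        cell_admin2[grid.cell_index(r, c)] = a2id
    return AdminHierarchy(units=pd.DataFrame(units), cell_admin2=cell_admin2)


def generate_world(config: WorldConfig, seed: int) -> World:
    """Generate a deterministic synthetic world for a (config, seed) pair."""
    rng = np.random.default_rng(seed)
    grid = Grid(config.nrows, config.ncols, config.cell_deg)
    admin = _build_hierarchy(config, grid)
    nyears = len(config.years)

    base_pop = rng.lognormal(config.pop_log_mean, config.pop_log_sd, grid.ncells)
    growth = (1.0 + config.pop_growth) ** np.arange(nyears)
    population = base_pop[:, None] * growth[None, :]

    coords = grid.coords()
    n_time_varying = int(round(config.n_covariates * config.time_varying_fraction))
    covariates: dict[str, np.ndarray] = {}
    standardization: dict[str, Standardization] = {}
    static_flags: dict[str, bool] = {}
    base_fields: list[np.ndarray] = []
    for j in range(config.n_covariates):
        spatial = sample_separable_field(
            coords, 1, config.covariate_range, 1.0, 0.0, rng
        )[0, :, 0]
        static = j >= n_time_varying
        if static:
            raw = np.repeat(spatial[:, None], nyears, axis=1)
        else:
            trend = rng.normal(0.0, 0.03)
            raw = spatial[:, None] + trend * np.arange(nyears)[None, :]
        base_fields.append(raw)
        _add_standardized(covariates, standardization, f"x{j:02d}", raw)
        static_flags[f"x{j:02d}"] = static
    # deliberately collinear covariates so the VIF filter has work to do
    for j in range(config.n_collinear):
        a, b = rng.choice(config.n_covariates, size=2, replace=False)
        lam = rng.uniform(0.3, 0.7)
        raw = lam * base_fields[a] + (1 - lam) * base_fields[b]
        raw = raw + rng.normal(0.0, 0.15, raw.shape)
        name = f"mix{j:02d}"
        _add_standardized(covariates, standardization, name, raw)
        static_flags[name] = False

    return World(
        grid=grid,
        years=tuple(config.years),
        admin=admin,
        population=population,
        covariates=covariates,
        covariate_standardization=standardization,
        covariate_static=static_flags,
    )


def _add_standardized(cov, std, name, raw):
    mean = float(raw.mean())
    sd = float(raw.std())
    if sd == 0.0:
        sd = 1.0
    cov[name] = (raw - mean) / sd
    std[name] = Standardization(mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# truth surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPParams:
    spatial_range: float = 6.0  # cells
    spatial_sd: float = 0.6
    temporal_rho: float = 0.8
    nugget_sd: float = 0.15

    def __post_init__(self):
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be positive")
        if self.spatial_sd < 0 or self.nugget_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 < self.temporal_rho < 1.0:
            raise ValueError("temporal_rho must lie in (-1, 1)")


@dataclass(frozen=True)
class TruthParams:
    intercept: float = -2.0
    beta: Mapping[str, float] = field(default_factory=dict)
    gp: GPParams = GPParams()


@dataclass
class TruthSurface:
    prevalence: np.ndarray  # (ncells, nyears) in (0, 1)
    logit_prevalence: np.ndarray
    gp_params: GPParams
    beta: dict[str, float]
    intercept: float


def simulate_truth(world: World, params: TruthParams, seed: int) -> TruthSurface:
    """Realise a truth surface: logit(p) = intercept + X beta + GP + nugget."""
    rng = np.random.default_rng(seed)
    eta = np.full((world.grid.ncells, world.nyears), params.intercept)
    for name, b in params.beta.items():
        eta = eta + b * world.covariates[name]
    gp = params.gp
    eta = eta + sample_separable_field(
        world.grid.coords(),
        world.nyears,
        gp.spatial_range,
        gp.spatial_sd,
        gp.temporal_rho,
        rng,
    )[0]
    if gp.nugget_sd > 0:
        eta = eta + rng.normal(0.0, gp.nugget_sd, eta.shape)
    return TruthSurface(
        prevalence=expit(eta),
        logit_prevalence=eta,
        gp_params=gp,
        beta=dict(params.beta),
        intercept=params.intercept,
    )


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyDesign:
    n_sources: int = 30
    clusters_per_source: int = 50
    children_per_cluster: int = 20
    polygon_fraction: float = 0.1
    year_gap_fraction: float = 0.2  # fraction of years with no surveys at all

    def __post_init__(self):
        for name in ("polygon_fraction", "year_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_sources < 1 or self.clusters_per_source < 1:
            raise ConfigurationError("survey design counts must be positive")


def _unit_prevalence(world, truth, unit_cells, year_idx) -> float:
    pop = world.population[unit_cells, year_idx]
    p = truth.prevalence[unit_cells, year_idx]
    tot = pop.sum()
    if tot <= 0:
        return float(p.mean())
    return float((p * pop).sum() / tot)


def simulate_surveys(
    world: World, truth: TruthSurface, design: SurveyDesign, seed: int
) -> pd.DataFrame:
    """Simulate cluster (point) and polygon survey records.

    Outcomes are Binomial(n_children, p) with p the truth prevalence at the
    record's cell-year; polygon records observe the population-weighted mean
    prevalence over their admin2 unit.  Returns a surveys table with the
    columns in ``SURVEY_COLUMNS``.
    """
    rng = np.random.default_rng(seed)
    nyears = world.nyears
    n_gap = int(round(design.year_gap_fraction * nyears))
    n_gap = min(n_gap, nyears - 1)  # always keep at least one surveyed year
    gap_years = set(
        rng.choice(nyears, size=n_gap, replace=False).tolist()
    ) if n_gap else set()
    open_years = [t for t in range(nyears) if t not in gap_years]

    countries = world.admin.units_at_level(0)
    admin2_by_country: dict[str, list[str]] = {c: [] for c in countries}
    for uid in world.admin.units_at_level(2):
        admin2_by_country[world.admin.country_of(uid)].append(uid)
    admin2_cells = world.admin.cell_membership(2)
    country_cells = world.admin.cell_membership(0)

    rows = []
    for s in range(design.n_sources):
        source_id = f"S{s:03d}"
        t = int(rng.choice(open_years))
        country = countries[int(rng.integers(len(countries)))]
        cells = country_cells[country]
        pop = world.population[cells, t]
        cell_prob = pop / pop.sum() if pop.sum() > 0 else None
        for _ in range(design.clusters_per_source):
            n_children = design.children_per_cluster
            if rng.random() < design.polygon_fraction:
                uid = admin2_by_country[country][
                    int(rng.integers(len(admin2_by_country[country])))
                ]
                p = _unit_prevalence(world, truth, admin2_cells[uid], t)
                rows.append(
                    (source_id, world.years[t], "polygon", -1, -1, uid,
                     n_children, int(rng.binomial(n_children, p)), 1.0)
                )
            else:
                cell = int(rng.choice(cells, p=cell_prob))
                p = truth.prevalence[cell, t]
                r, c = world.grid.rowcol(cell)
                rows.append(
                    (source_id, world.years[t], "point", int(r), int(c),
                     world.admin.cell_admin2[cell],
                     n_children, int(rng.binomial(n_children, p)), 1.0)
                )
    df = pd.DataFrame(
        rows,
        columns=["source_id", "year", "geometry_kind", "cell_row", "cell_col",
                 "admin_unit_id", "n_children", "n_cases", "weight"],
    )
    return df


def validate_surveys(df: pd.DataFrame, world: World | None = None) -> None:
    """Raise ValueError (citing row numbers) for records violating invariants."""
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"surveys table missing required columns: {missing}")
    bad = df.index[df["n_cases"] > df["n_children"]]
    if len(bad):
        raise ValueError(
            f"n_cases > n_children on line {int(bad[0]) + 2} "
            f"(row index {int(bad[0])})"
        )
    if (df["n_children"] <= 0).any():
        raise ValueError("n_children must be positive for every record")
    if world is not None:
        pts = df[df["geometry_kind"] == "point"]
        out = (
            (pts["cell_row"] < 0) | (pts["cell_row"] >= world.grid.nrows)
            | (pts["cell_col"] < 0) | (pts["cell_col"] >= world.grid.ncols)
        )
        if out.any():
            raise ValueError("point record references an out-of-grid cell")
        polys = df[df["geometry_kind"] == "polygon"]
        known = set(world.admin.units["unit_id"])
        unknown = set(polys["admin_unit_id"]) - known
        if unknown:
            raise ValueError(f"polygon records reference unknown units: {sorted(unknown)}")


def survey_cell_index(df: pd.DataFrame, grid: Grid) -> np.ndarray:
    """Flat cell index for point records (-1 for polygon records)."""
    idx = df["cell_row"].to_numpy() * grid.ncols + df["cell_col"].to_numpy()
    return np.where(df["geometry_kind"].to_numpy() == "point", idx, -1)


# ---------------------------------------------------------------------------
# national inputs and risk factors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskFactorSpec:
    name: str
    group: str  # protect | prevent | treat
    rr_range: tuple[float, float]
    exposure_base_range: tuple[float, float] = (0.3, 0.7)
    exposure_trend_per_year: float = -0.012
    spatial_sd: float = 0.1

    def __post_init__(self):
        if self.group not in ("protect", "prevent", "treat"):
            raise ConfigurationError(f"unknown risk group {self.group!r}")
        if self.rr_range[0] <= 0:
            raise ConfigurationError("risk ratios must be positive")


DEFAULT_RISK_SPECS = (
    RiskFactorSpec("stunting", "protect", (1.5, 2.5)),
    RiskFactorSpec("wasting", "protect", (1.5, 2.5)),
    RiskFactorSpec("unimproved_sanitation", "prevent", (1.3, 2.0)),
    RiskFactorSpec("unimproved_water", "prevent", (1.3, 2.0)),
    RiskFactorSpec("no_ors", "treat", (1.5, 2.5)),
)


@dataclass(frozen=True)
class NationalParams:
    cfr_range: tuple[float, float] = (5e-4, 3e-3)  # deaths per episode
    cfr_annual_decline: float = 0.02
    epsilon: float = 0.1  # envelope perturbation half-width
    duration_days: float = 4.2  # mean episode duration used for the envelopes
    risk_specs: tuple[RiskFactorSpec, ...] = DEFAULT_RISK_SPECS

    def __post_init__(self):
        lo, hi = self.cfr_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"cfr_range must lie in [0, 1], got {self.cfr_range}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class NationalInputs:
    """Per (country, year) envelopes and case-fatality rates.

    ``table`` columns: country, year, envelope_prevalence, envelope_incidence
    (episodes per child-year), envelope_mortality (deaths per child-year), cfr.
    """

    table: pd.DataFrame

    def __post_init__(self):
        self._idx = self.table.set_index(["country", "year"])

    def cfr(self, country: str, year: int) -> float:
        try:
            return float(self._idx.at[(country, year), "cfr"])
        except KeyError:
            raise KeyError(f"no case-fatality rate for ({country}, {year})")

    def envelope(self, measure: str) -> pd.Series:
        return self._idx[f"envelope_{measure}"]


@dataclass
class RiskFactor:
    name: str
    group: str  # protect | prevent | treat
    exposure: np.ndarray  # (ncells, nyears) in [0, 1]
    rr: float

    def __post_init__(self):
        if not np.isfinite(self.rr) or self.rr <= 0:
            raise ValueError(f"risk ratio must be finite and positive, got {self.rr}")
        if self.exposure.min() < 0 or self.exposure.max() > 1:
            raise ValueError(f"exposure for {self.name!r} outside [0, 1]")


def national_truth_aggregates(world: World, truth: TruthSurface) -> pd.DataFrame:
    """Population-weighted national mean prevalence per country-year."""
    rows = []
    for country, cells in world.admin.cell_membership(0).items():
        pop = world.population[cells, :]
        prev = truth.prevalence[cells, :]
        agg = (prev * pop).sum(axis=0) / pop.sum(axis=0)
        for t, year in enumerate(world.years):
            rows.append({"country": country, "year": year, "prevalence": agg[t]})
    return pd.DataFrame(rows)


def simulate_national_inputs(
    world: World,
    truth: TruthSurface,
    params: NationalParams,
    seed: int,
) -> tuple[NationalInputs, list[RiskFactor]]:
    """National envelopes perturbed around the truth, plus risk-factor surfaces.

    Envelopes are the truth's population-weighted national aggregates times
    (1 + eps) with eps ~ U[-epsilon, epsilon] drawn independently for the
    prevalence and incidence measures; mortality is envelope_incidence * CFR by
    construction, so raking against these tables has a known consistent target.
    CFRs are constant subnationally with a deterministic annual decline.
    """
    rng = np.random.default_rng(seed)
    nat = national_truth_aggregates(world, truth)
    rows = []
    cfr_base = {
        c: rng.uniform(*params.cfr_range) for c in world.admin.units_at_level(0)
    }
    for _, rec in nat.iterrows():
        country, year, prev = rec["country"], int(rec["year"]), rec["prevalence"]
        t = world.year_index(year)
        e_prev = rng.uniform(-params.epsilon, params.epsilon)
        e_inc = rng.uniform(-params.epsilon, params.epsilon)
        cfr = cfr_base[country] * (1.0 - params.cfr_annual_decline) ** t
        inc = prev * DAYS_PER_YEAR / params.duration_days * (1.0 + e_inc)
        rows.append(
            {
                "country": country,
                "year": year,
                "envelope_prevalence": prev * (1.0 + e_prev),
                "envelope_incidence": inc,
                "envelope_mortality": inc * cfr,
                "cfr": cfr,
            }
        )
    inputs = NationalInputs(table=pd.DataFrame(rows))

    coords = world.grid.coords()
    factors = []
    for spec in params.risk_specs:
        rr = float(rng.uniform(*spec.rr_range))
        base = rng.uniform(*spec.exposure_base_range)
        if spec.spatial_sd > 0:
            spatial = sample_separable_field(
                coords, 1, max(world.grid.nrows / 3.0, 1.0), spec.spatial_sd, 0.0, rng
            )[0, :, 0]
        else:
            spatial = np.zeros(world.grid.ncells)
        trend = spec.exposure_trend_per_year * np.arange(world.nyears)
        exposure = np.clip(base + spatial[:, None] + trend[None, :], 0.0, 1.0)
        factors.append(RiskFactor(spec.name, spec.group, exposure, rr))
    return inputs, factors
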