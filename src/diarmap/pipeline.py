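"""Configuration and orchestration: one reproducible end-to-end pipeline.

Stages (each re-runnable from the previous stage's saved outputs):

    simulate -> prep -> stack -> fit -> post -> aggregate -> counterfactual
    (validate runs the source-stratified cross-validation on the side)

Every stage writes its outputs under the run directory and records them in
``manifest.json`` together with the seed, the full configuration and content
hashes, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__, io
from .burden import apply_cfr, prevalence_to_incidence, rake
from .counterfactual import averted_deaths
from .covprep import resample_polygons, vif_filter
from .geomodel import (
    FitConfig,
    PrevalenceDraws,
    Priors,
    cross_validate,
    fit_geostat,
    sample_posterior,
)
from .inequality import aggregate, classify_change, deviations, gini, top_risk_units
from .stacker import LEARNER_FAMILIES, StackResult, fit_stack
from .worldgen import (
    GPParams,
    NationalParams,
    RiskFactorSpec,
    SurveyDesign,
    TruthParams,
    WorldConfig,
    generate_world,
    simulate_national_inputs,
    simulate_surveys,
    simulate_truth,
)

__all__ = ["PipelineConfig", "desk_config", "run_pipeline", "StageError", "STAGES"]

log = logging.getLogger("diarmap")

STAGES = ("simulate", "prep", "stack", "fit", "post", "aggregate",
          "counterfactual", "validate")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults follow the published constants
    (250 draws, 4.2-day episode duration, VIF threshold 3, five folds,
    2.5/97.5 percentiles)."""

    seed: int = 0
    world: WorldConfig = field(default_factory=WorldConfig)
    truth: TruthParams = field(default_factory=TruthParams)
    surveys: SurveyDesign = field(default_factory=SurveyDesign)
    national: NationalParams = field(default_factory=NationalParams)
    n_draws: int = 250
    duration_days: float = 4.2
    vif_threshold: float = 3.0
    resample_k: int = 10
    n_folds: int = 5
    learners: tuple[str, ...] = LEARNER_FAMILIES
    fit: FitConfig = field(default_factory=FitConfig)
    cv_fit: FitConfig = field(
        default_factory=lambda: FitConfig(max_fev=30, hyper_samples=1)
    )
    priors: Priors = field(default_factory=Priors)
    prevalence_rake_mode: str = "logit"
    rate_rake_mode: str = "multiplicative"
    no_rake_countries: tuple[str, ...] = ()
    change_threshold: float = 0.10
    change_mode: str = "annualised"
    dominance_share: float = 0.5
    top_risk_fraction: float = 0.20
    cv_draws: int = 100

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "world" in d:
            w = dict(d["world"])
            if "years" in w:
                w["years"] = tuple(w["years"])
            d["world"] = WorldConfig(**w)
        if "truth" in d:
            t = dict(d["truth"])
            if "gp" in t:
                t["gp"] = GPParams(**t["gp"])
            d["truth"] = TruthParams(**t)
        if "surveys" in d:
            d["surveys"] = SurveyDesign(**d["surveys"])
        if "national" in d:
            n = dict(d["national"])
            if "cfr_range" in n:
                n["cfr_range"] = tuple(n["cfr_range"])
            if "risk_specs" in n:
                n["risk_specs"] = tuple(
                    RiskFactorSpec(**{**s, "rr_range": tuple(s["rr_range"]),
                                      "exposure_base_range": tuple(s["exposure_base_range"])})
                    for s in n["risk_specs"]
                )
            d["national"] = NationalParams(**n)
        for key in ("fit", "cv_fit"):
            if key in d:
                f = dict(d[key])
                if "init" in f:
                    f["init"] = GPParams(**f["init"])
                d[key] = FitConfig(**f)
        if "priors" in d:
            d["priors"] = Priors(**d["priors"])
        for key in ("learners", "no_rake_countries"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Make a nested structure YAML-safe (tuples -> lists, numpy -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def desk_config(seed: int = 0, n_draws: int = 50) -> PipelineConfig:
    """Desk-scale preset: 20x20 grid, 3 countries, 6 years, reduced draws."""
    return PipelineConfig(
        seed=seed,
        world=WorldConfig(nrows=20, ncols=20, years=tuple(range(2012, 2018)),
                          n_countries=3, n_covariates=6, n_collinear=2),
        truth=TruthParams(
            intercept=-1.8,
            beta={"x00": 0.5, "x01": -0.35, "x02": 0.25},
            gp=GPParams(spatial_range=5.0, spatial_sd=0.5,
                        temporal_rho=0.8, nugget_sd=0.12),
        ),
        surveys=SurveyDesign(n_sources=30, clusters_per_source=50,
                             children_per_cluster=25, polygon_fraction=0.1),
        n_draws=n_draws,
        fit=FitConfig(max_fev=40),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


class _Run:
    """A pipeline run rooted at a directory, with manifest bookkeeping."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path):
        self.config = config
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {
                "seed": config.seed,
                "version": __version__,
                "config": _plain(config.to_dict()),
                "outputs": {},
                "stages": {},
            }

    def record(self, stage: str, paths: list[Path], t0: float, **info) -> None:
        for p in paths:
            self.manifest["outputs"][p.name] = _sha256(p)
        self.manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2), **info,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def path(self, name: str) -> Path:
        return self.dir / name


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_simulate(run: _Run):
    t0 = time.time()
    cfg = run.config
    world = generate_world(cfg.world, cfg.seed)
    truth = simulate_truth(world, cfg.truth, cfg.seed + 1)
    surveys = simulate_surveys(world, truth, cfg.surveys, cfg.seed + 2)
    inputs, factors = simulate_national_inputs(world, truth, cfg.national,
                                               cfg.seed + 3)
    io.save_world(world, run.path("world"))
    ds = xr.Dataset(
        {"prevalence": (("cell", "year"), truth.prevalence),
         "logit_prevalence": (("cell", "year"), truth.logit_prevalence)},
        coords={"year": list(world.years)},
    )
    ds.to_netcdf(run.path("truth.nc"), engine="scipy")
    io.write_surveys(surveys, run.path("surveys.csv"))
    io.write_national_inputs(inputs, run.path("national_inputs.csv"))
    io.write_risk_factors(factors, run.path("risk_factors.csv"),
                          run.path("risk_exposures.nc"), world.years)
    run.record("simulate", [run.path("surveys.csv"),
                            run.path("national_inputs.csv"),
                            run.path("risk_factors.csv")], t0,
               n_records=len(surveys))
    log.info("simulate: %d survey records over %d cells x %d years",
             len(surveys), world.grid.ncells, world.nyears)
    return world, truth, surveys, inputs, factors


def stage_prep(run: _Run, world=None, surveys=None):
    t0 = time.time()
    cfg = run.config
    world = world if world is not None else io.load_world(run.path("world"))
    if surveys is None:
        surveys = io.read_surveys(run.path("surveys.csv"), world)
    cov_table = pd.DataFrame(
        {n: world.covariates[n].ravel() for n in sorted(world.covariates)}
    )
    report = vif_filter(cov_table, threshold=cfg.vif_threshold)
    pd.DataFrame({"covariate": report.retained}).to_csv(
        run.path("covariates_retained.csv"), index=False
    )
    points = resample_polygons(surveys, world, k=cfg.resample_k,
                               seed=cfg.seed + 4)
    io.write_surveys(points, run.path("surveys_points.csv"))
    run.record("prep", [run.path("covariates_retained.csv"),
                        run.path("surveys_points.csv")], t0,
               retained=len(report.retained), dropped=report.dropped)
    log.info("prep: retained %d covariates (dropped %s); %d point records",
             len(report.retained), report.dropped or "none", len(points))
    return world, points, report.retained


def stage_stack(run: _Run, world=None, points=None, retained=None):
    t0 = time.time()
    cfg = run.config
    world = world if world is not None else io.load_world(run.path("world"))
    if points is None:
        points = io.read_surveys(run.path("surveys_points.csv"), world)
    if retained is None:
        retained = pd.read_csv(run.path("covariates_retained.csv"))[
            "covariate"].tolist()
    stack = fit_stack(points, world, retained, n_folds=cfg.n_folds,
                      learners=cfg.learners, seed=cfg.seed + 5)
    oos = stack.oos.copy()
    oos.insert(0, "fold", stack.folds)
    oos.insert(0, "record", np.arange(len(oos)))
    oos.to_csv(run.path("stack_oos.csv"), index=False)
    ds = xr.Dataset(
        {"surface": (("learner", "cell", "year"),
                     np.stack([stack.surfaces[n] for n in stack.learner_names]))},
        coords={"learner": stack.learner_names, "year": list(world.years)},
    )
    ds.to_netcdf(run.path("stack_surfaces.nc"), engine="scipy")
    run.record("stack", [run.path("stack_oos.csv")], t0,
               learners=stack.learner_names)
    log.info("stack: %d learners fit on %d records", len(stack.learner_names),
             len(points))
    return world, points, stack


def _load_stack(run: _Run, world) -> tuple[pd.DataFrame, StackResult]:
    points = io.read_surveys(run.path("surveys_points.csv"), world)
    oos = pd.read_csv(run.path("stack_oos.csv"))
    ds = xr.open_dataset(run.path("stack_surfaces.nc"), engine="scipy")
    names = [str(n) for n in ds["learner"].values]
    surfaces = {n: ds["surface"].values[i] for i, n in enumerate(names)}
    ds.close()
    retained = pd.read_csv(run.path("covariates_retained.csv"))["covariate"].tolist()
    stack = StackResult(
        learner_names=names,
        oos=oos[names],
        folds=oos["fold"].to_numpy(),
        surfaces=surfaces,
        covariate_names=retained,
    )
    return points, stack


def stage_fit(run: _Run, world=None, points=None, stack=None):
    t0 = time.time()
    cfg = run.config
    world = world if world is not None else io.load_world(run.path("world"))
    if stack is None or points is None:
        points, stack = _load_stack(run, world)
    fit = fit_geostat(points, world, stack, priors=cfg.priors, config=cfg.fit,
                      seed=cfg.seed + 6)
    draws = sample_posterior(fit, n_draws=cfg.n_draws, seed=cfg.seed + 7)
    io.save_draws(draws, run.path("draws_prevalence_unraked.nc"))
    mean, (lo, hi) = draws.mean(), draws.interval()
    ds = xr.Dataset(
        {"mean": (("cell", "year"), mean),
         "lower": (("cell", "year"), lo),
         "upper": (("cell", "year"), hi)},
        coords={"year": list(world.years)},
    )
    ds.to_netcdf(run.path("prevalence_summary.nc"), engine="scipy")
    pd.DataFrame([{
        "learner": n, "weight": w
    } for n, w in zip(fit.learner_names, fit.weights)]).to_csv(
        run.path("stack_weights.csv"), index=False)
    run.record("fit", [run.path("stack_weights.csv")], t0,
               **{k: (v if isinstance(v, (int, bool)) else float(v))
                  for k, v in fit.diagnostics.items()})
    log.info("fit: weights=%s gp=%s", dict(zip(fit.learner_names, fit.weights)),
             fit.gp_params)
    return world, fit, draws


def stage_post(run: _Run, world=None, draws=None):
    """Rake prevalence, derive + rake incidence, derive mortality."""
    t0 = time.time()
    cfg = run.config
    world = world if world is not None else io.load_world(run.path("world"))
    if draws is None:
        draws = io.load_draws(run.path("draws_prevalence_unraked.nc"))
    inputs = io.read_national_inputs(run.path("national_inputs.csv"))
    cell_country = world.admin.cell_country()
    exclude = set(cfg.no_rake_countries)

    prev, f_prev = rake(draws, world.population, inputs.envelope("prevalence"),
                        cell_country, mode=cfg.prevalence_rake_mode,
                        exclude=exclude)
    inc = prevalence_to_incidence(prev, duration=cfg.duration_days)
    inc, f_inc = rake(inc, world.population, inputs.envelope("incidence"),
                      cell_country, mode=cfg.rate_rake_mode, exclude=exclude)
    mort = apply_cfr(inc, inputs, cell_country)
    mort, f_mort = rake(mort, world.population, inputs.envelope("mortality"),
                        cell_country, mode=cfg.rate_rake_mode, exclude=exclude)

    for cube, name in ((prev, "prevalence"), (inc, "incidence"), (mort, "mortality")):
        io.save_draws(cube, run.path(f"draws_{name}.nc"))
    factors = pd.concat([
        f_prev.table.assign(measure="prevalence", mode=f_prev.mode),
        f_inc.table.assign(measure="incidence", mode=f_inc.mode),
        f_mort.table.assign(measure="mortality", mode=f_mort.mode),
    ])
    factors.to_csv(run.path("raking_factors.csv"), index=False)
    run.record("post", [run.path("raking_factors.csv")], t0)
    log.info("post: raked %d draws for 3 measures", prev.n_draws)
    return world, {"prevalence": prev, "incidence": inc, "mortality": mort}


def stage_aggregate(run: _Run, world=None, cubes=None):
    t0 = time.time()
    cfg = run.config
    world = world if world is not None else io.load_world(run.path("world"))
    if cubes is None:
        cubes = {m: io.load_draws(run.path(f"draws_{m}.nc"))
                 for m in ("prevalence", "incidence", "mortality")}
    summaries, devs, ginis = [], [], []
    aggs = {}
    for measure, cube in cubes.items():
        ag0 = aggregate(cube, world.population, world.admin, 0)
        ag1 = aggregate(cube, world.population, world.admin, 1)
        ag2 = aggregate(cube, world.population, world.admin, 2)
        aggs[measure] = (ag0, ag1, ag2)
        for ag in (ag0, ag1, ag2):
            summaries.append(ag.summary())
        devs.append(deviations(ag0, ag2, world.admin))
        s2 = ag2.summary()
        for year in cube.years:
            sy = s2[s2["year"] == year]
            ginis.append({
                "measure": measure, "year": year,
                "gini": gini(sy["mean"].to_numpy(), sy["population"].to_numpy()),
            })
    summary = pd.concat(summaries, ignore_index=True)
    summary[summary["level"] == 2].to_csv(run.path("admin2_estimates.csv"),
                                          index=False)
    summary[summary["level"] == 1].to_csv(run.path("admin1_estimates.csv"),
                                          index=False)
    summary[summary["level"] == 0].to_csv(run.path("country_estimates.csv"),
                                          index=False)
    pd.concat(devs, ignore_index=True).to_csv(run.path("deviations.csv"),
                                              index=False)
    pd.DataFrame(ginis).to_csv(run.path("gini.csv"), index=False)

    mort2 = aggs["mortality"][2]
    year0, year1 = world.years[0], world.years[-1]
    change = classify_change(mort2, year0, year1,
                             threshold=cfg.change_threshold,
                             mode=cfg.change_mode)
    change.units.assign(
        share_declining_mean=change.share_declining_mean,
        share_declining_lower=change.share_declining_lower,
        share_declining_upper=change.share_declining_upper,
    ).to_csv(run.path("change_classes.csv"), index=False)
    s_last = mort2.summary()
    s_last = s_last[s_last["year"] == year1]
    top = top_risk_units(s_last, fraction=cfg.top_risk_fraction)
    pd.DataFrame({"unit_id": top}).to_csv(run.path("top_risk_units.csv"),
                                          index=False)
    io.write_geojson_join(
        world,
        s_last[["unit_id", "mean", "lower", "upper", "population"]],
        run.path("admin2_mortality.geojson"),
    )
    run.record("aggregate", [run.path("admin2_estimates.csv"),
                             run.path("admin1_estimates.csv"),
                             run.path("country_estimates.csv"),
                             run.path("deviations.csv"), run.path("gini.csv"),
                             run.path("change_classes.csv"),
                             run.path("top_risk_units.csv")], t0)
    log.info("aggregate: %d admin2 unit-years summarised",
             int((summary["level"] == 2).sum()))
    return world, aggs, change


def stage_counterfactual(run: _Run, world=None, cubes=None):
    t0 = time.time()
    cfg = run.config
    world = world if world is not None else io.load_world(run.path("world"))
    mort = (cubes["mortality"] if cubes is not None
            else io.load_draws(run.path("draws_mortality.nc")))
    factors = io.read_risk_factors(run.path("risk_factors.csv"),
                                   run.path("risk_exposures.nc"))
    year_ref, year_obs = world.years[0], world.years[-1]
    t_ref, t_obs = 0, world.nyears - 1
    result = averted_deaths(
        mort.values[:, t_obs, :], world.population[:, t_obs], factors,
        world.admin, t_ref, t_obs, year_ref, year_obs,
        dominance_share=cfg.dominance_share,
    )
    result.units.to_csv(run.path("counterfactual_units.csv"), index=False)
    io.write_geojson_join(
        world,
        result.units[["unit_id", "averted_mean", "averted_per_1000",
                      "dominant_driver"]],
        run.path("counterfactual_drivers.geojson"),
    )
    run.record("counterfactual", [run.path("counterfactual_units.csv")], t0,
               averted_total=result.totals["averted_mean"])
    log.info("counterfactual: %.1f deaths averted (mean) vs %d exposures",
             result.totals["averted_mean"], year_ref)
    return result


def stage_validate(run: _Run, world=None, points=None):
    t0 = time.time()
    cfg = run.config
    world = world if world is not None else io.load_world(run.path("world"))
    if points is None:
        points = io.read_surveys(run.path("surveys_points.csv"), world)
    retained = pd.read_csv(run.path("covariates_retained.csv"))["covariate"].tolist()
    report = cross_validate(points, world, retained, n_folds=cfg.n_folds,
                            learners=cfg.learners, priors=cfg.priors,
                            config=cfg.cv_fit, n_draws=cfg.cv_draws,
                            seed=cfg.seed + 8)
    metrics = report.fold_metrics.copy()
    pooled = pd.DataFrame([{"fold": "pooled", **report.pooled}])
    pd.concat([metrics, pooled], ignore_index=True).to_csv(
        run.path("cv_metrics.csv"), index=False)
    run.record("validate", [run.path("cv_metrics.csv")], t0, **report.pooled)
    log.info("validate: pooled %s", report.pooled)
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 validate: bool = True) -> dict:
    """Execute every stage; returns the in-memory artifact bundle."""
    run = _Run(config, out_dir)
    stage = "simulate"
    try:
        world, truth, surveys, inputs, factors = stage_simulate(run)
        stage = "prep"
        world, points, retained = stage_prep(run, world, surveys)
        stage = "stack"
        world, points, stack = stage_stack(run, world, points, retained)
        stage = "fit"
        world, fit, draws = stage_fit(run, world, points, stack)
        stage = "post"
        world, cubes = stage_post(run, world, draws)
        stage = "aggregate"
        world, aggs, change = stage_aggregate(run, world, cubes)
        stage = "counterfactual"
        cf = stage_counterfactual(run, world, cubes)
        report = None
        if validate:
            stage = "validate"
            report = stage_validate(run, world, points)
    except (StageError, KeyboardInterrupt):
        raise
    except Exception as err:
        raise StageError(stage, str(err)) from err
    return {
        "world": world, "truth": truth, "surveys": surveys, "points": points,
        "national_inputs": inputs, "risk_factors": factors, "stack": stack,
        "fit": fit, "draws": draws, "cubes": cubes, "aggregates": aggs,
        "change": change, "counterfactual": cf, "cv": report,
        "manifest": run.manifest, "dir": run.dir,
    }
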