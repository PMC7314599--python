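import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diarmap.geomodel import PrevalenceDraws
from diarmap.worldgen import (
    GPParams,
    SurveyDesign,
    TruthParams,
    WorldConfig,
    generate_world,
    simulate_surveys,
    simulate_truth,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world():
    """10x10 grid, 2 countries, 3 years: cheap shared world."""
    cfg = WorldConfig(
        nrows=10, ncols=10, years=(2015, 2016, 2017),
        n_countries=2, n_admin1_per_country=2, n_admin2_per_admin1=2,
        n_covariates=4, n_collinear=1,
    )
    return generate_world(cfg, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_world):
    params = TruthParams(
        intercept=-1.6,
        beta={"x00": 0.4, "x01": -0.3},
        gp=GPParams(spatial_range=3.0, spatial_sd=0.4, temporal_rho=0.7,
                    nugget_sd=0.1),
    )
    return simulate_truth(small_world, params, seed=8)


@pytest.fixture(scope="session")
def small_surveys(small_world, small_truth):
    design = SurveyDesign(n_sources=12, clusters_per_source=25,
                          children_per_cluster=25, polygon_fraction=0.1,
                          year_gap_fraction=0.0)
    return simulate_surveys(small_world, small_truth, design, seed=9)


def perturbed_draws(truth, years=None, n_draws=20, scale=0.2, seed=0):
    """Cheap stand-in draw cube: truth jittered on the logit scale."""
    rng = np.random.default_rng(seed)
    eta = truth.logit_prevalence[:, :, None] + rng.normal(
        0.0, scale, truth.prevalence.shape + (n_draws,)
    )
    if years is None:
        years = tuple(range(2000, 2000 + truth.prevalence.shape[1]))
    return PrevalenceDraws(
        values=1.0 / (1.0 + np.exp(-eta)),
        years=tuple(years),
        measure="prevalence",
    )
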