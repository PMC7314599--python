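"""World generator: admin partitioning, truth surfaces, surveys, envelopes."""

import numpy as np
import pytest
from scipy.special import expit

from diarmap.gp import grid_coords, matern32_correlation, sample_separable_field
from diarmap.worldgen import (
    ConfigurationError,
    GPParams,
    NationalParams,
    RiskFactorSpec,
    SurveyDesign,
    TruthParams,
    TruthSurface,
    WorldConfig,
    generate_world,
    simulate_national_inputs,
    simulate_surveys,
    simulate_truth,
    validate_surveys,
)


def _constant_truth(world, p):
    prev = np.full((world.grid.ncells, world.nyears), float(p))
    eta = np.full_like(prev, np.log(p / (1 - p)) if 0 < p < 1 else -np.inf)
    return TruthSurface(prevalence=prev, logit_prevalence=eta,
                        gp_params=GPParams(), beta={}, intercept=0.0)


class TestGenerateWorld:
    def test_degenerate_single_cell_world(self):
        cfg = WorldConfig(nrows=1, ncols=1, years=(2017,), n_countries=1,
                          n_admin1_per_country=1, n_admin2_per_admin1=1,
                          n_covariates=1, n_collinear=0)
        world = generate_world(cfg, seed=0)
        assert world.grid.ncells == 1
        assert len(world.admin.units_at_level(2)) == 1
        assert world.admin.cell_admin2[0] == world.admin.units_at_level(2)[0]

    def test_determinism(self):
        cfg = WorldConfig(nrows=8, ncols=8, years=(2016, 2017), n_countries=2)
        w1 = generate_world(cfg, seed=3)
        w2 = generate_world(cfg, seed=3)
        assert np.array_equal(w1.population, w2.population)
        for name in w1.covariates:
            assert np.array_equal(w1.covariates[name], w2.covariates[name])
        assert np.array_equal(w1.admin.cell_admin2, w2.admin.cell_admin2)

    def test_admin2_units_partition_grid(self):
        cfg = WorldConfig(nrows=40, ncols=40, years=(2017,), n_countries=3,
                          n_admin1_per_country=2, n_admin2_per_admin1=2)
        world = generate_world(cfg, seed=1)
        membership = world.admin.cell_membership(2)
        assert len(membership) == 12
        counts = np.zeros(world.grid.ncells, dtype=int)
        for cells in membership.values():
            counts[cells] += 1
        assert (counts == 1).all()  # exhaustive, disjoint
        # parent chain of every admin2 reaches exactly one country
        for uid in membership:
            assert world.admin.country_of(uid) in world.admin.units_at_level(0)

    def test_population_positive_and_heavy_tailed(self):
        cfg = WorldConfig(nrows=20, ncols=20, years=(2017,))
        world = generate_world(cfg, seed=2)
        pop = world.population[:, 0]
        assert (pop > 0).all() and np.isfinite(pop).all()
        # a few cells dominate: top 10% of cells hold well over 10% of people
        top = np.sort(pop)[-len(pop) // 10:].sum()
        assert top / pop.sum() > 0.3

    @pytest.mark.parametrize("bad", [
        dict(n_countries=0), dict(n_admin2_per_admin1=0), dict(n_covariates=0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            WorldConfig(nrows=5, ncols=5, **bad)


class TestSimulateTruth:
    def test_all_zero_parameters_give_half(self, small_world):
        params = TruthParams(intercept=0.0, beta={},
                             gp=GPParams(spatial_sd=0.0, nugget_sd=0.0))
        truth = simulate_truth(small_world, params, seed=0)
        assert np.allclose(truth.prevalence, 0.5)

    def test_intercept_only_matches_inverse_logit(self, small_world):
        params = TruthParams(intercept=-2.944, beta={},
                             gp=GPParams(spatial_sd=0.0, nugget_sd=0.0))
        truth = simulate_truth(small_world, params, seed=0)
        assert np.allclose(truth.prevalence, 0.050, atol=1e-3)

    def test_linear_predictor_identity(self, small_world):
        """logit(prevalence) equals intercept + X beta + GP + nugget exactly."""
        params = TruthParams(intercept=-1.2, beta={"x00": 0.7},
                             gp=GPParams(spatial_sd=0.3, nugget_sd=0.05))
        truth = simulate_truth(small_world, params, seed=4)
        assert np.allclose(expit(truth.logit_prevalence), truth.prevalence)
        assert truth.prevalence.min() > 0 and truth.prevalence.max() < 1

    @pytest.mark.parametrize("bad", [
        dict(temporal_rho=1.0), dict(temporal_rho=-1.5),
        dict(spatial_sd=-0.1), dict(spatial_range=0.0),
    ])
    def test_invalid_gp_params(self, bad):
        with pytest.raises(ValueError):
            GPParams(**bad)


class TestGPSampler:
    def test_marginal_variance_recovered(self):
        """Empirical variance at distance 0 within 15% of sd^2 = 1."""
        coords = grid_coords(6, 6)
        fields = sample_separable_field(coords, 1, spatial_range=8.0,
                                        spatial_sd=1.0, temporal_rho=0.0,
                                        rng=np.random.default_rng(0),
                                        n_samples=500)
        var0 = fields[:, :, 0].var(axis=0).mean()
        assert abs(var0 - 1.0) < 0.15

    def test_correlation_decays_with_distance(self):
        """Mean empirical correlation < 0.2 beyond 3x the range parameter."""
        nr = nc = 15
        coords = grid_coords(nr, nc)
        rng_par = 2.0
        fields = sample_separable_field(coords, 1, rng_par, 1.0, 0.0,
                                        np.random.default_rng(1),
                                        n_samples=150)[:, :, 0]
        centered = fields - fields.mean(axis=0)
        sd = centered.std(axis=0)
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        corr = (centered.T @ centered) / len(fields)
        corr = corr / np.outer(sd, sd)
        far = d > 3 * rng_par
        near = (d > 0.5) & (d < 1.5)
        assert abs(corr[far].mean()) < 0.2
        assert corr[near].mean() > corr[far].mean()  # monotone-ish decay

    def test_matern_correlation_bounds(self):
        r = matern32_correlation(grid_coords(4, 4), 3.0)
        assert np.allclose(np.diag(r), 1.0)
        assert (r <= 1.0 + 1e-12).all() and (r > 0).all()


class TestSimulateSurveys:
    def test_zero_prevalence_gives_zero_cases(self, small_world):
        truth = _constant_truth(small_world, 1e-300)
        truth.prevalence[:] = 0.0
        df = simulate_surveys(small_world, truth,
                              SurveyDesign(n_sources=5, clusters_per_source=10),
                              seed=0)
        assert (df["n_cases"] == 0).all()

    def test_pooled_fraction_concentrates(self, small_world):
        """10 000 clusters x 20 children at p=0.2: pooled fraction ~ 0.2."""
        truth = _constant_truth(small_world, 0.2)
        design = SurveyDesign(n_sources=200, clusters_per_source=50,
                              children_per_cluster=20, polygon_fraction=0.0,
                              year_gap_fraction=0.0)
        df = simulate_surveys(small_world, truth, design, seed=1)
        frac = df["n_cases"].sum() / df["n_children"].sum()
        assert 0.195 <= frac <= 0.205

    def test_polygon_records_use_population_weighted_mean(self):
        cfg = WorldConfig(nrows=1, ncols=2, years=(2017,), n_countries=1,
                          n_admin1_per_country=1, n_admin2_per_admin1=1,
                          n_covariates=1, n_collinear=0)
        world = generate_world(cfg, seed=0)
        world.population[:, 0] = 100.0  # equal population
        truth = _constant_truth(world, 0.5)
        truth.prevalence[0, 0], truth.prevalence[1, 0] = 0.1, 0.3
        design = SurveyDesign(n_sources=40, clusters_per_source=50,
                              children_per_cluster=100, polygon_fraction=1.0,
                              year_gap_fraction=0.0)
        df = simulate_surveys(world, truth, design, seed=2)
        assert (df["geometry_kind"] == "polygon").all()
        frac = df["n_cases"].sum() / df["n_children"].sum()
        assert abs(frac - 0.2) < 0.005  # binomial mean at the weighted p

    def test_records_are_valid(self, small_world, small_surveys):
        validate_surveys(small_surveys, small_world)
        assert (small_surveys["n_cases"] <= small_surveys["n_children"]).all()

    def test_validation_rejects_impossible_counts(self, small_surveys):
        bad = small_surveys.copy()
        bad.loc[5, "n_cases"] = bad.loc[5, "n_children"] + 1
        with pytest.raises(ValueError, match="line 7"):
            validate_surveys(bad)


class TestNationalInputs:
    def test_zero_perturbation_matches_truth_aggregate(self, small_world,
                                                       small_truth):
        params = NationalParams(epsilon=0.0)
        inputs, _ = simulate_national_inputs(small_world, small_truth, params,
                                             seed=0)
        cells = small_world.admin.cell_membership(0)
        for country, cidx in cells.items():
            pop = small_world.population[cidx, :]
            prev = small_truth.prevalence[cidx, :]
            expected = (prev * pop).sum(axis=0) / pop.sum(axis=0)
            got = inputs.table.set_index(["country", "year"])
            for t, year in enumerate(small_world.years):
                assert got.at[(country, year), "envelope_prevalence"] == pytest.approx(
                    expected[t], rel=1e-12)

    def test_zero_cfr_gives_zero_mortality_envelope(self, small_world,
                                                    small_truth):
        params = NationalParams(cfr_range=(0.0, 0.0))
        inputs, _ = simulate_national_inputs(small_world, small_truth, params,
                                             seed=0)
        assert (inputs.table["envelope_mortality"] == 0).all()

    def test_mortality_envelope_consistency(self, small_world, small_truth):
        inputs, _ = simulate_national_inputs(small_world, small_truth,
                                             NationalParams(), seed=1)
        t = inputs.table
        assert np.allclose(t["envelope_mortality"],
                           t["envelope_incidence"] * t["cfr"], atol=1e-9)

    def test_exposure_trend_arithmetic(self):
        """-0.02/year from 0.6 over 17 years lands at 0.26 in every cell."""
        cfg = WorldConfig(nrows=4, ncols=4, years=tuple(range(2000, 2018)),
                          n_countries=1, n_admin1_per_country=1,
                          n_admin2_per_admin1=1, n_covariates=1, n_collinear=0)
        world = generate_world(cfg, seed=0)
        truth = _constant_truth(world, 0.1)
        spec = RiskFactorSpec("stunting", "protect", rr_range=(2.0, 2.0),
                              exposure_base_range=(0.6, 0.6),
                              exposure_trend_per_year=-0.02, spatial_sd=0.0)
        params = NationalParams(risk_specs=(spec,))
        _, factors = simulate_national_inputs(world, truth, params, seed=0)
        assert np.allclose(factors[0].exposure[:, -1], 0.26)
        assert np.allclose(factors[0].exposure[:, 0], 0.6)

    def test_cfr_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            NationalParams(cfr_range=(0.5, 1.5))
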