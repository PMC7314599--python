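"""Aggregation, uncertainty intervals, Gini, change classes, top-risk units."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diarmap.geomodel import PrevalenceDraws
from diarmap.inequality import (
    AggregatedEstimates,
    aggregate,
    classify_change,
    deviations,
    gini,
    top_risk_units,
)
from diarmap.worldgen import WorldConfig, generate_world

from conftest import perturbed_draws


def brute_force_gini(rates, pops):
    w = pops / pops.sum()
    mu = (w * rates).sum()
    if mu == 0:
        return 0.0
    total = 0.0
    for i in range(len(rates)):
        for j in range(len(rates)):
            total += w[i] * w[j] * abs(rates[i] - rates[j])
    return total / (2 * mu)


def _unit_estimates(values, population, years=(2017,), level=2):
    values = np.asarray(values, dtype=float)
    return AggregatedEstimates(
        unit_ids=[f"U{i}" for i in range(values.shape[0])],
        level=level, years=years, measure="mortality",
        values=values, population=np.asarray(population, dtype=float),
    )


class TestAggregate:
    def test_uniform_rate_at_every_level(self, small_world):
        draws = PrevalenceDraws(
            values=np.full((small_world.grid.ncells, small_world.nyears, 5), 0.23),
            years=small_world.years,
        )
        for level in (0, 1, 2):
            agg = aggregate(draws, small_world.population, small_world.admin,
                            level)
            assert np.allclose(agg.values, 0.23)

    def test_two_cell_weighted_mean(self):
        cfg = WorldConfig(nrows=1, ncols=2, years=(2017,), n_countries=1,
                          n_admin1_per_country=1, n_admin2_per_admin1=1,
                          n_covariates=1, n_collinear=0)
        world = generate_world(cfg, seed=0)
        world.population[:, 0] = [100.0, 300.0]
        draws = PrevalenceDraws(
            values=np.array([[[0.1]], [[0.3]]]), years=(2017,))
        agg = aggregate(draws, world.population, world.admin, 2)
        assert agg.values[0, 0, 0] == pytest.approx(0.25)

    def test_conservation_across_levels(self, small_world, small_truth):
        """Per draw, admin2 counts sum to admin1 counts sum to national."""
        draws = perturbed_draws(small_truth, years=small_world.years,
                                n_draws=8, seed=3)
        counts = {}
        for level in (0, 1, 2):
            agg = aggregate(draws, small_world.population, small_world.admin,
                            level)
            counts[level] = agg.counts().sum(axis=0)  # (nyears, ndraws)
        assert np.allclose(counts[2], counts[1], rtol=1e-8)
        assert np.allclose(counts[1], counts[0], rtol=1e-8)

    def test_mismatched_population_rejected(self, small_world):
        draws = PrevalenceDraws(
            values=np.zeros((small_world.grid.ncells, small_world.nyears, 2)),
            years=small_world.years)
        with pytest.raises(ValueError, match="population shape"):
            aggregate(draws, small_world.population[:-1], small_world.admin, 2)

    def test_percentile_interval_oracle(self):
        """Draws 1..250: linear-interpolation UI is (7.225, 243.775)."""
        est = _unit_estimates(np.arange(1, 251, dtype=float).reshape(1, 1, 250),
                              [[1.0]])
        s = est.summary()
        assert s["lower"].iloc[0] == pytest.approx(7.225)
        assert s["upper"].iloc[0] == pytest.approx(243.775)

    def test_multiplicative_raking_commutes_with_aggregation(self, small_world,
                                                             small_truth):
        from diarmap.burden import rake

        draws = perturbed_draws(small_truth, years=small_world.years,
                                n_draws=5, seed=4)
        env = pd.Series(
            0.15,
            index=pd.MultiIndex.from_product(
                [small_world.admin.units_at_level(0), small_world.years],
                names=["country", "year"]),
        )
        cell_country = small_world.admin.cell_country()
        raked, factors = rake(draws, small_world.population, env, cell_country,
                              mode="multiplicative")
        agg_then = aggregate(raked, small_world.population, small_world.admin, 0)
        agg_first = aggregate(draws, small_world.population, small_world.admin, 0)
        ftab = factors.table.set_index(["country", "year", "draw"])["factor"]
        for i, c in enumerate(agg_first.unit_ids):
            for t, y in enumerate(small_world.years):
                for k in range(5):
                    scaled = agg_first.values[i, t, k] * ftab.loc[(c, y, k)]
                    assert scaled == pytest.approx(agg_then.values[i, t, k],
                                                   rel=1e-12)


class TestDeviations:
    def _pair(self, unit_rate, country_rate, hierarchy_world):
        country = hierarchy_world.admin.units_at_level(0)[0]
        unit = [u for u in hierarchy_world.admin.units_at_level(2)
                if hierarchy_world.admin.country_of(u) == country][0]
        agg_c = AggregatedEstimates(
            unit_ids=[country], level=0, years=(2017,), measure="incidence",
            values=np.full((1, 1, 10), country_rate),
            population=np.ones((1, 1)))
        agg_u = AggregatedEstimates(
            unit_ids=[unit], level=2, years=(2017,), measure="incidence",
            values=np.full((1, 1, 10), unit_rate),
            population=np.ones((1, 1)))
        return deviations(agg_c, agg_u, hierarchy_world.admin)

    def test_absolute_deviation_worked_example(self, small_world):
        """Unit at 6.3 vs national 4.0 episodes per child-year: +2.3."""
        dev = self._pair(6.3, 4.0, small_world)
        assert dev["absolute_mean"].iloc[0] == pytest.approx(2.3)

    def test_unit_equal_to_country(self, small_world):
        dev = self._pair(0.5, 0.5, small_world)
        assert dev["absolute_mean"].iloc[0] == pytest.approx(0.0)
        assert dev["ratio_mean"].iloc[0] == pytest.approx(1.0)
        assert dev["relative_mean_pct"].iloc[0] == pytest.approx(0.0)

    def test_relative_deviation_worked_example(self, small_world):
        """0.80 vs 0.437 deaths per 1000: ratio 1.831, +83.1%."""
        dev = self._pair(0.80, 0.437, small_world)
        assert dev["ratio_mean"].iloc[0] == pytest.approx(1.831, abs=5e-4)
        assert dev["relative_mean_pct"].iloc[0] == pytest.approx(83.1, abs=0.05)

    def test_zero_country_rate_leaves_ratio_missing(self, small_world):
        dev = self._pair(0.4, 0.0, small_world)
        assert dev["absolute_mean"].iloc[0] == pytest.approx(0.4)
        assert np.isnan(dev["ratio_mean"].iloc[0])

    def test_per_draw_minimum_ratio_retained(self, small_world):
        """'At least X% higher in every draw' statements are reproducible."""
        country = small_world.admin.units_at_level(0)[0]
        unit = [u for u in small_world.admin.units_at_level(2)
                if small_world.admin.country_of(u) == country][0]
        rng = np.random.default_rng(0)
        c_vals = rng.uniform(1.0, 2.0, size=(1, 1, 50))
        u_vals = c_vals * rng.uniform(1.86, 2.5, size=(1, 1, 50))
        agg_c = AggregatedEstimates([country], 0, (2017,), "incidence",
                                    c_vals, np.ones((1, 1)))
        agg_u = AggregatedEstimates([unit], 2, (2017,), "incidence",
                                    u_vals, np.ones((1, 1)))
        dev = deviations(agg_c, agg_u, small_world.admin)
        assert dev["ratio_min"].iloc[0] >= 1.86
        assert dev["ratio_min"].iloc[0] == pytest.approx(
            (u_vals / c_vals).min())


class TestGini:
    def test_equality_gives_zero(self):
        assert gini(np.full(10, 0.3), np.random.default_rng(0).uniform(1, 5, 10)
                    ) == pytest.approx(0.0, abs=1e-15)

    def test_two_unit_closed_form(self):
        """Equal population, rates (0, x): G = 0.5 for any x > 0."""
        for x in (0.1, 1.0, 7.3):
            assert gini(np.array([0.0, x]), np.array([1.0, 1.0])
                        ) == pytest.approx(0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        rates = rng.uniform(0, 5, 50)
        pops = rng.uniform(0.1, 10, 50)
        assert gini(rates, pops) == pytest.approx(
            brute_force_gini(rates, pops), abs=1e-12)

    @given(c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(2)
        rates = rng.uniform(0.1, 3, 20)
        pops = rng.uniform(1, 10, 20)
        assert gini(c * rates, pops) == pytest.approx(gini(rates, pops),
                                                      rel=1e-9)

    def test_equal_weight_upper_bound(self):
        """G is bounded by (n-1)/n for n equal-weight units."""
        n = 8
        rates = np.zeros(n)
        rates[0] = 1.0  # most unequal configuration
        g = gini(rates, np.ones(n))
        assert g <= (n - 1) / n + 1e-12
        assert g == pytest.approx((n - 1) / n)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gini(np.array([-0.1, 0.2]), np.array([1.0, 1.0]))

    def test_zero_mean_returns_zero(self):
        assert gini(np.zeros(4), np.ones(4)) == 0.0


class TestClassifyChange:
    def test_constant_series_no_decline(self):
        est = _unit_estimates(np.full((3, 2, 10), 0.4), np.ones((3, 2)),
                              years=(2000, 2017))
        res = classify_change(est, 2000, 2017)
        assert (res.units["mean_change"] == 0).all()
        assert not res.units["declined"].any()
        assert res.share_declining_mean == 0.0

    def test_halving_is_four_percent_annualised(self):
        vals = np.empty((1, 2, 5))
        vals[:, 0, :] = 0.8
        vals[:, 1, :] = 0.4
        est = _unit_estimates(vals, np.ones((1, 2)), years=(2000, 2017))
        res = classify_change(est, 2000, 2017, mode="annualised")
        assert res.units["mean_change"].iloc[0] == pytest.approx(
            0.5 ** (1 / 17) - 1, abs=1e-12)
        assert res.units["mean_change"].iloc[0] == pytest.approx(-0.0400,
                                                                 abs=5e-4)

    def test_all_units_declining_gives_degenerate_share(self):
        vals = np.empty((4, 2, 6))
        vals[:, 0, :] = 1.0
        vals[:, 1, :] = 1.0 - 0.12
        est = _unit_estimates(vals, np.ones((4, 2)), years=(2016, 2017))
        res = classify_change(est, 2016, 2017, threshold=0.10, mode="total")
        assert res.share_declining_mean == 1.0
        assert res.share_declining_lower == res.share_declining_upper == 1.0

    def test_annualised_and_total_agree_in_sign(self):
        # single draw per unit: the sign property holds draw by draw
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.1, 1.0, size=(10, 2, 1))
        est = _unit_estimates(vals, np.ones((10, 2)), years=(2000, 2017))
        ann = classify_change(est, 2000, 2017, mode="annualised")
        tot = classify_change(est, 2000, 2017, mode="total")
        assert np.array_equal(np.sign(ann.units["mean_change"]),
                              np.sign(tot.units["mean_change"]))

    def test_zero_baseline_draws_excluded(self):
        vals = np.ones((1, 2, 4))
        vals[0, 0, :2] = 0.0
        est = _unit_estimates(vals, np.ones((1, 2)), years=(2016, 2017))
        res = classify_change(est, 2016, 2017)
        assert res.units["n_excluded_draws"].iloc[0] == 2


class TestTopRiskUnits:
    def _summary(self, rates, pops):
        return pd.DataFrame({
            "unit_id": [f"U{i}" for i in range(len(rates))],
            "mean": rates, "population": pops,
        })

    def test_single_unit_any_fraction(self):
        s = self._summary([0.5], [100.0])
        for f in (0.01, 0.5, 1.0):
            assert top_risk_units(s, f) == ["U0"]

    def test_equal_population_top_two_of_ten(self):
        rates = np.linspace(1.0, 0.1, 10)
        s = self._summary(rates, np.full(10, 10.0))
        assert top_risk_units(s, 0.2) == ["U0", "U1"]

    def test_fraction_one_returns_all_positive_population(self):
        s = self._summary([0.3, 0.2, 0.1], [10.0, 0.0, 5.0])
        assert set(top_risk_units(s, 1.0)) == {"U0", "U2"}

    def test_boundary_unit_included(self):
        s = self._summary([0.9, 0.8, 0.1], [15.0, 50.0, 35.0])
        assert top_risk_units(s, 0.2) == ["U0", "U1"]

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            top_risk_units(self._summary([0.1], [0.0]), 0.2)
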