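"""VIF computation/filtering and polygon-to-point resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diarmap.covprep import (
    ResamplingError,
    compute_vif,
    largest_remainder,
    resample_polygons,
    vif_filter,
)
from diarmap.worldgen import WorldConfig, generate_world


def _statsmodels_vif(x: np.ndarray) -> np.ndarray:
    """Independent oracle: per-column OLS R^2 via statsmodels."""
    import statsmodels.api as sm

    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        others = sm.add_constant(np.delete(x, j, axis=1))
        r2 = sm.OLS(x[:, j], others).fit().rsquared
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _orthogonal_frame():
    a = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    b = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
    b = b - a * (a @ b) / (a @ a)
    return pd.DataFrame({"a": a, "b": b})


class TestComputeVif:
    def test_orthogonal_columns_have_unit_vif(self):
        vif = compute_vif(_orthogonal_frame())
        assert vif["a"] == pytest.approx(1.0, abs=1e-10)
        assert vif["b"] == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_column_is_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=20)})
        vif = compute_vif(df)
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_constant_column_is_infinite(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        assert np.isinf(compute_vif(df)["a"])

    def test_matches_ols_oracle_on_correlated_design(self):
        """Known pairwise correlation 0.8: agree with the regression oracle."""
        rng = np.random.default_rng(1)
        n = 400
        raw = rng.normal(size=(n, 3))
        raw -= raw.mean(axis=0)
        # whiten empirically, then impose the target correlation exactly
        cov = raw.T @ raw / n
        white = raw @ np.linalg.inv(np.linalg.cholesky(cov)).T
        target = np.full((3, 3), 0.8)
        np.fill_diagonal(target, 1.0)
        x = white @ np.linalg.cholesky(target).T
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        got = np.array([compute_vif(df)[c] for c in df.columns])
        assert np.allclose(got, _statsmodels_vif(x), atol=1e-8)

    def test_rank_error(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(3, 4)))
        with pytest.raises(ValueError, match="rank"):
            compute_vif(df)

    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-20.0, 20.0))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        base = compute_vif(df)
        df2 = df.copy()
        df2["b"] = df2["b"] * scale + shift
        rescaled = compute_vif(df2)
        for c in "abc":
            assert rescaled[c] == pytest.approx(base[c], rel=1e-6)


class TestVifFilter:
    def test_orthogonal_all_retained(self):
        report = vif_filter(_orthogonal_frame(), threshold=3.0)
        assert sorted(report.retained) == ["a", "b"]
        assert report.dropped == []

    def test_duplicated_pair_keeps_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        report = vif_filter(df)
        assert report.dropped == ["a"]  # alphabetical tie-break
        assert set(report.retained) == {"b", "c"}

    def test_matches_stepwise_greedy_oracle(self):
        """Six correlated columns: retained set equals a re-derived greedy path."""
        rng = np.random.default_rng(3)
        base = rng.normal(size=(200, 3))
        cols = {
            "a": base[:, 0],
            "b": base[:, 0] * 0.9 + rng.normal(size=200) * 0.3,
            "c": base[:, 1],
            "d": base[:, 1] * 0.8 + base[:, 0] * 0.4 + rng.normal(size=200) * 0.2,
            "e": base[:, 2],
            "f": base[:, 2] * 0.95 + rng.normal(size=200) * 0.2,
        }
        df = pd.DataFrame(cols)
        report = vif_filter(df, threshold=3.0)
        # independent greedy recomputation with the statsmodels oracle
        current = list(df.columns)
        while len(current) > 1:
            vifs = dict(zip(current, _statsmodels_vif(df[current].to_numpy())))
            worst_v = max(vifs.values())
            if worst_v <= 3.0:
                break
            current.remove(sorted(k for k, v in vifs.items() if v == worst_v)[0])
        assert report.retained == current
        assert max(report.vif.values()) <= 3.0

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(100, 2))
        df = pd.DataFrame({
            "a": base[:, 0],
            "b": base[:, 0] + rng.normal(size=100) * 0.1,
            "c": base[:, 1],
        })
        first = vif_filter(df)
        second = vif_filter(df[first.retained])
        assert second.retained == first.retained
        assert second.dropped == []

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            vif_filter(pd.DataFrame())

    def test_per_region_filter_gives_region_specific_sets(self):
        from diarmap.covprep import vif_filter_by_region

        rng = np.random.default_rng(6)
        # region A: a ~ b collinear; region B: independent columns
        a = rng.normal(size=200)
        df = pd.DataFrame({
            "a": a, "b": np.concatenate([
                a[:100] + rng.normal(0, 0.05, 100), rng.normal(size=100)]),
            "c": rng.normal(size=200),
        })
        regions = np.repeat(["A", "B"], 100)
        reports = vif_filter_by_region(df, regions)
        assert reports["A"].dropped == ["a"]
        assert reports["B"].dropped == []


class TestLargestRemainder:
    def test_worked_example(self):
        got = largest_remainder(101, np.array([0.5, 0.3, 0.2]))
        assert got.tolist() == [51, 30, 20]

    @given(total=st.integers(0, 10_000), k=st.integers(1, 8),
           seed=st.integers(0, 100))
    def test_total_conserved(self, total, k, seed):
        rng = np.random.default_rng(seed)
        shares = rng.dirichlet(np.ones(k))
        got = largest_remainder(total, shares)
        assert got.sum() == total
        assert (got >= 0).all()


@pytest.fixture(scope="module")
def poly_world():
    cfg = WorldConfig(nrows=6, ncols=6, years=(2016, 2017), n_countries=1,
                      n_admin1_per_country=2, n_admin2_per_admin1=2,
                      n_covariates=2, n_collinear=0)
    return generate_world(cfg, seed=11)


def _poly_record(world, uid, n_children=100, n_cases=30, year=2017):
    return pd.DataFrame([{
        "source_id": "S0", "year": year, "geometry_kind": "polygon",
        "cell_row": -1, "cell_col": -1, "admin_unit_id": uid,
        "n_children": n_children, "n_cases": n_cases, "weight": 1.0,
    }])


class TestResamplePolygons:
    def test_single_cell_unit_round_trips(self):
        cfg = WorldConfig(nrows=1, ncols=1, years=(2017,), n_countries=1,
                          n_admin1_per_country=1, n_admin2_per_admin1=1,
                          n_covariates=1, n_collinear=0)
        world = generate_world(cfg, seed=0)
        uid = world.admin.units_at_level(2)[0]
        out = resample_polygons(_poly_record(world, uid), world, k=5, seed=0)
        assert len(out) == 1
        assert out.iloc[0]["geometry_kind"] == "point"
        assert out.iloc[0]["n_children"] == 100
        assert out.iloc[0]["n_cases"] == 30

    def test_equal_population_even_split(self):
        cfg = WorldConfig(nrows=1, ncols=2, years=(2017,), n_countries=1,
                          n_admin1_per_country=1, n_admin2_per_admin1=1,
                          n_covariates=1, n_collinear=0)
        world = generate_world(cfg, seed=0)
        world.population[:, :] = 50.0
        uid = world.admin.units_at_level(2)[0]
        out = resample_polygons(_poly_record(world, uid, n_children=100),
                                world, k=2, seed=1)
        assert sorted(out["n_children"]) == [50, 50]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation(self, poly_world, small_world, seed, small_surveys):
        out = resample_polygons(small_surveys, small_world, k=4, seed=seed)
        assert out["n_children"].sum() == small_surveys["n_children"].sum()
        assert out["n_cases"].sum() == small_surveys["n_cases"].sum()
        assert (out["geometry_kind"] == "point").all()
        assert (out["n_cases"] <= out["n_children"]).all()

    def test_zero_population_unit_names_unit(self, poly_world):
        uid = poly_world.admin.units_at_level(2)[0]
        world = poly_world
        saved = world.population.copy()
        try:
            cells = world.admin.cell_membership(2)[uid]
            world.population[cells, :] = 0.0
            with pytest.raises(ResamplingError, match=uid.replace(".", r"\.")):
                resample_polygons(_poly_record(world, uid), world, k=3, seed=0)
        finally:
            world.population[:] = saved
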