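"""Through-origin regression, ANOVA, segmentation and health aggregation.

The regression is cross-checked against statsmodels OLS without a constant
(same slope, classical standard error and uncentered R²), and the ANOVA
against scipy's F test — the library routines serve as independent oracles
for the package's own implementations.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.base import clone

from cobenefits import (
    AnovaResult,
    GeneratorParams,
    SegmentSpec,
    ThroughOriginRegression,
    aggregate_health,
    fit_through_origin,
    generate,
    one_way_anova,
    per_capita_summary,
    sectorwise_fits,
    segment,
    stats,
)


class TestThroughOriginRegression:
    def test_noiseless_line_recovered_exactly(self):
        x = np.arange(1.0, 6.0)
        res = fit_through_origin(x, 2.0 * x)
        assert res.alpha == pytest.approx(2.0, rel=1e-15)
        assert res.r_squared == pytest.approx(1.0, rel=1e-15)
        assert res.alpha_ci[0] == pytest.approx(res.alpha_ci[1])
        assert not res.degenerate

    def test_single_point_slope_exact_but_ci_degenerate(self):
        res = fit_through_origin([1.0], [3.0])
        assert res.alpha == 3.0
        assert res.degenerate
        assert np.isnan(res.alpha_ci[0])

    def test_closed_form_slope(self):
        res = fit_through_origin([1, 2, 3], [2, 4.1, 5.9])
        assert res.alpha == pytest.approx(27.9 / 14, rel=1e-12)

    def test_all_zero_x_is_degenerate_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_through_origin([0.0, 0.0], [1.0, 2.0])

    def test_matches_statsmodels_no_constant_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        x = rng.uniform(0.1, 10, 80)
        y = 1.7 * x + rng.normal(0, 0.5, 80)
        res = fit_through_origin(x, y)
        ols = sm.OLS(y, x).fit()
        assert res.alpha == pytest.approx(ols.params[0], rel=1e-10)
        assert res.r_squared == pytest.approx(ols.rsquared, rel=1e-10)
        # statsmodels uses n-k = n-1 dof here as well
        assert res.se == pytest.approx(ols.bse[0], rel=1e-10)
        lo, hi = ols.conf_int()[0]
        assert res.alpha_ci == pytest.approx((lo, hi), rel=1e-10)

    def test_sklearn_estimator_contract(self):
        est = ThroughOriginRegression(conf_level=0.9, se_method="hc1")
        assert est.get_params() == {"conf_level": 0.9, "se_method": "hc1"}
        cloned = clone(est)
        x = np.linspace(1, 5, 20).reshape(-1, 1)
        cloned.fit(x, 3.0 * x.ravel())
        assert cloned.alpha_ == pytest.approx(3.0)
        assert cloned.predict(np.array([[2.0]]))[0] == pytest.approx(6.0)
        assert cloned.score(x, 3.0 * x.ravel()) == pytest.approx(1.0)

    def test_cluster_interval_wider_than_classical_under_shared_noise(self):
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(30), 10)
        x = 10 ** rng.uniform(0, 3, 300)
        city_effect = rng.lognormal(0, 0.3, 30)[groups]
        y = 2.0 * x * city_effect
        classical = fit_through_origin(x, y, se_method="classical")
        cluster = fit_through_origin(x, y, se_method="cluster", groups=groups)
        assert (cluster.alpha_ci[1] - cluster.alpha_ci[0]) > (
            classical.alpha_ci[1] - classical.alpha_ci[0]
        )

    def test_cluster_requires_groups(self):
        with pytest.raises(ValueError, match="groups"):
            fit_through_origin([1, 2], [1, 2], se_method="cluster")


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_sums_of_squares(self):
        res = one_way_anova({"A": [1, 2, 3], "B": [2, 3, 4]})
        assert res.f_stat == pytest.approx(1.5, rel=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(i, 1, 20) for i, k in enumerate("abc")}
        shifted = {k: v + 17.3 for k, v in groups.items()}
        assert one_way_anova(groups).f_stat == pytest.approx(
            one_way_anova(shifted).f_stat, rel=1e-9
        )

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(i * 0.3, 1, 25) for i, k in enumerate("abcd")}
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(f, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_small_group_dropped_with_warning_then_error_if_too_few(self):
        with pytest.warns(UserWarning, match="dropping group"):
            res = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "tiny": [5]})
        assert set(res.group_sizes) == {"a", "b"}
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                one_way_anova({"a": [1, 2, 3], "tiny": [5]})


class TestSegmentation:
    def test_population_threshold_split(self, toy):
        spec = SegmentSpec(variable="population", rule=200_000.0, labels=("large", "small"))
        parts = segment(toy, spec)
        assert {c for c in parts["large"].cities} == {"beta"}
        assert {c for c in parts["small"].cities} == {"alpha"}

    def test_city_at_threshold_goes_below(self, toy):
        spec = SegmentSpec(variable="population", rule=300_000.0, labels=("large", "small"))
        parts = segment(toy, spec)
        assert "beta" in parts["small"].cities

    def test_median_rule_uses_distinct_cities(self):
        dataset, _ = generate(GeneratorParams(seed=2, n_cities=20))
        spec = SegmentSpec(variable="pm25_level", rule="median", labels=("high", "low"))
        parts = segment(dataset, spec)
        med = np.median([c.pm25_level for c in dataset.cities.values()])
        for c in parts["high"].cities.values():
            assert c.pm25_level > med
        for c in parts["low"].cities.values():
            assert c.pm25_level <= med

    def test_partition_property(self, default_draw):
        dataset, _ = default_draw
        spec = SegmentSpec(variable="population", rule=200_000.0, labels=("large", "small"))
        parts = segment(dataset, spec)
        ids = [m.measure_id for ds in parts.values() for m in ds.measures]
        assert len(ids) == len(dataset.measures)
        assert len(set(ids)) == len(ids)


class TestSectorwiseFits:
    def test_noiseless_per_sector_slopes_recovered(self):
        rng = np.random.default_rng(0)
        slopes = {"Buildings": 0.20, "Traffic": 1.66}
        rows = []
        for sector, a in slopes.items():
            x = 10 ** rng.uniform(-4, -1, 50)
            for xi in x:
                rows.append({"sector": sector, "ccb": xi, "aqb_nox": a * xi, "city_id": "c"})
        table = pd.DataFrame(rows)
        fits = sectorwise_fits(table, "ccb", "aqb_nox")
        for sector, a in slopes.items():
            assert fits[sector].alpha == pytest.approx(a, rel=1e-12)
            assert fits[sector].r_squared == pytest.approx(1.0)
        assert not fits["all"].degenerate

    def test_pooled_equals_sector_fit_with_single_sector(self):
        x = np.linspace(0.001, 0.01, 30)
        table = pd.DataFrame(
            {"sector": "Traffic", "ccb": x, "aqb_nox": 1.66 * x, "city_id": "c"}
        )
        fits = sectorwise_fits(table, "ccb", "aqb_nox")
        assert fits["all"].alpha == pytest.approx(fits["Traffic"].alpha, rel=1e-14)

    def test_low_r2_sectors_flagged_not_dropped(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 1.5, 200)
        # zero-mean noise unrelated to x: uncentered R^2 stays near zero
        noise_y = rng.normal(0.0, 2.0, 200)
        table = pd.DataFrame(
            {"sector": "Industry", "ccb": x, "aqb_nox": noise_y, "city_id": "c"}
        )
        fits = sectorwise_fits(table, "ccb", "aqb_nox", min_r2=0.4)
        assert "Industry" in fits
        assert fits["Industry"].flagged_low_r2

    def test_tiny_sector_reported_degenerate(self):
        table = pd.DataFrame(
            {"sector": ["Other"], "ccb": [0.1], "aqb_nox": [0.2], "city_id": ["c"]}
        )
        fits = sectorwise_fits(table, "ccb", "aqb_nox")
        assert fits["Other"].degenerate


class TestPerCapitaSummary:
    def test_hand_cases(self, toy):
        one = toy.subset([m for m in toy.measures if m.measure_id == "m1"])
        # m1: 1300 t in a city of 100k -> 0.013 t/cap
        out = per_capita_summary({"only": one})
        assert out["only"][0] == pytest.approx(1300.0)
        assert out["only"][1] == pytest.approx(0.013)

    def test_unweighted_mean_over_measures(self):
        dataset, _ = generate(GeneratorParams(seed=9, n_cities=5))
        sub = dataset.subset(dataset.measures[:2])
        m1, m2 = sub.measures
        expected_abs = ((m1.co2_reduction or 0) + (m2.co2_reduction or 0)) / 2
        out = per_capita_summary({"s": sub})
        assert out["s"][0] == pytest.approx(expected_abs)

    def test_small_cities_save_more_per_capita(self, es_table):
        filtered, _, _ = es_table
        spec = SegmentSpec(variable="population", rule=200_000.0, labels=("large", "small"))
        out = per_capita_summary(segment(filtered, spec))
        assert out["small"][1] > out["large"][1]


class TestAggregateHealth:
    def test_empty_table_gives_zeros(self):
        table = pd.DataFrame(
            columns=["sector", "pd_low", "pd_central", "pd_high",
                     "yls_low", "yls_central", "yls_high"]
        )
        out = aggregate_health(table)
        assert out.iloc[0]["pd_central"] == 0.0

    def test_sector_rows_sum_to_total_bound_by_bound(self, es_table):
        _, _, table = es_table
        out = aggregate_health(table, group_by="sector")
        total = out[out["group"] == "all"].iloc[0]
        sectors = out[out["group"] != "all"]
        for col in ("pd_low", "pd_central", "pd_high", "yls_low", "yls_central", "yls_high"):
            assert total[col] == pytest.approx(sectors[col].sum(), rel=1e-12)

    def test_totals_equal_brute_force_sum(self, es_table):
        _, _, table = es_table
        out = aggregate_health(table)
        assert out.iloc[0]["yls_high"] == pytest.approx(
            float(np.sum(table["yls_high"].to_numpy())), rel=1e-12
        )
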