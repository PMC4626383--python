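"""Assumption-routed factor tests, band contrasts, polynomial fits and the
individual-vs-cumulative comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mosaicweb.inference import (
    band_contrast,
    factor_effects,
    fit_polynomial,
    individual_vs_cumulative,
)
from mosaicweb.net_core import admitted, pool
from mosaicweb.synthetic_data import generate_mosaic, null_effect_config
from mosaicweb.topology_metrics import metrics_table


def _table(values_by_group, column="altitude", metric="P"):
    rows = []
    for g, values in values_by_group.items():
        for k, v in enumerate(values):
            rows.append({"unit": f"{g}_{k}", column: g,
                         "month" if column == "altitude" else "altitude": 0,
                         "precipitation": 0.0, metric: v})
    return pd.DataFrame(rows)


class TestFactorEffects:
    def test_normal_homoscedastic_routes_to_anova(self, rng):
        groups = {2200 + 100 * g: rng.normal(10, 1, size=12) for g in range(4)}
        (res,) = factor_effects(_table(groups), "altitude", metrics=["P"])
        assert res.test_used == "anova"
        assert res.normality_p >= 0.05 and res.homogeneity_p >= 0.05

    def test_assumption_violation_routes_to_kruskal(self, rng):
        # strongly heteroscedastic groups
        groups = {2200: rng.normal(10, 0.01, size=15),
                  2300: rng.normal(10, 8.0, size=15),
                  2400: rng.normal(10, 0.01, size=15)}
        (res,) = factor_effects(_table(groups), "altitude", metrics=["P"])
        assert res.test_used == "kruskal_wallis"

    def test_routing_is_pure_function_of_assumptions(self, rng):
        for trial in range(20):
            groups = {2200 + 100 * g: rng.normal(0, rng.uniform(0.5, 3), size=8)
                      for g in range(3)}
            (res,) = factor_effects(_table(groups), "altitude", metrics=["P"])
            expected = ("anova" if res.normality_p >= 0.05
                        and res.homogeneity_p >= 0.05 else "kruskal_wallis")
            assert res.test_used == expected

    def test_constant_metric_is_degenerate(self):
        groups = {2200: [3, 3, 3], 2300: [3, 3, 3]}
        (res,) = factor_effects(_table(groups), "altitude", metrics=["P"])
        assert res.test_used == "degenerate"
        assert np.isnan(res.p_value)

    def test_requires_two_observations_per_level(self):
        groups = {2200: [1.0], 2300: [2.0, 3.0]}
        with pytest.raises(ValueError):
            factor_effects(_table(groups), "altitude", metrics=["P"])

    def test_injected_time_effect_detected_over_altitude(self):
        """A mosaic with a strong precipitation-driven month effect on plant
        richness and no altitude structure should yield smaller time than
        altitude p-values for P in nearly every replicate."""
        wins = usable = 0
        for seed in range(20):
            config = null_effect_config(
                seed, richness_response=(0.0, -0.5), empty_unit_rate=0.0)
            units, _ = generate_mosaic(config)
            table = metrics_table(admitted(units))
            ok = True
            for col in ("altitude", "month"):
                sizes = table.groupby(col).size()
                if len(sizes) < 2 or (sizes < 2).any():
                    ok = False
            if not ok:
                continue
            usable += 1
            p_alt = factor_effects(table, "altitude", metrics=["P"])[0].p_value
            p_time = factor_effects(table, "time", metrics=["P"])[0].p_value
            wins += p_time < p_alt
        assert usable >= 15
        assert wins / usable >= 0.9


class TestBandContrast:
    def test_identical_bands_give_zero_t(self):
        table = _table({2200: [1, 2, 3], 2800: [1, 2, 3]})
        (res,) = band_contrast(table, metrics=["P"])
        assert res.statistic == pytest.approx(0.0)
        assert res.mean_low == res.mean_high

    def test_large_variance_ratio_selects_welch(self, rng):
        table = _table({2200: rng.normal(0, 1, 40), 2800: rng.normal(0, 16, 40)})
        (res,) = band_contrast(table, metrics=["P"])
        assert res.test_used == "welch_t"
        assert res.levene_p < 0.05

    def test_homogeneous_bands_select_pooled(self, rng):
        table = _table({2200: rng.normal(0, 1, 40), 2800: rng.normal(0.2, 1, 40)})
        (res,) = band_contrast(table, metrics=["P"])
        assert res.test_used == "pooled_t"

    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        for _ in range(200):
            table = _table({2200: rng.normal(5, 2, 10), 2500: rng.normal(5, 2, 12),
                            2800: rng.normal(5, 2, 8)})
            (res,) = band_contrast(table, metrics=["P"])
            rejections += res.p_value < 0.05
        assert 2 <= rejections <= 20  # binomial(200, 0.05)

    def test_thin_band_errors(self):
        table = _table({2200: [1, 2, 3], 2800: [1.0]})
        with pytest.raises(ValueError):
            band_contrast(table, metrics=["P"])


class TestFitPolynomial:
    def test_exact_line_recovered(self):
        x = np.array([2200, 2300, 2400, 2500, 2600, 2700, 2800, 2900], float)
        y = -0.44 + 0.0003 * x
        fit = fit_polynomial(y, x, degree=1)
        assert fit.coefficients[0] == pytest.approx(-0.44, abs=1e-10)
        assert fit.coefficients[1] == pytest.approx(0.0003, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noise_only_p_values_uniform(self, rng):
        pvals = []
        for _ in range(200):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            pvals.append(fit_polynomial(y, x, 1).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_curvature_sign(self, rng):
        x = np.linspace(-3, 3, 40)
        concave = fit_polynomial(-(x ** 2) + rng.normal(0, 0.1, 40), x, 2)
        convex = fit_polynomial(x ** 2 + rng.normal(0, 0.1, 40), x, 2)
        assert concave.curvature == "concave"
        assert convex.curvature == "convex"

    def test_prediction_matches_coefficients(self):
        x = np.array([0.0, 1, 2, 3, 4])
        y = 2 - x + 0.5 * x ** 2
        fit = fit_polynomial(y, x, 2)
        assert fit.predict(x) == pytest.approx(y)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            fit_polynomial([1, 2, 3], [5, 5, 5], 1)
        with pytest.raises(ValueError):
            fit_polynomial([1, 2], [1, 2], 1)


class TestIndividualVsCumulative:
    def test_pooled_richness_dominates_members(self, default_mosaics):
        units, _ = default_mosaics[0]
        individual = metrics_table(admitted(units))
        for axis in ("altitude", "month"):
            pooled = pool(units, by=axis)
            cumulative = metrics_table(admitted(pooled))
            for _, row in cumulative.iterrows():
                key = "altitude" if axis == "altitude" else "month"
                members = individual[individual[key] == row[key]]
                if len(members):
                    assert row["S"] >= members["S"].max()

    def test_cumulative_connectance_lower(self, default_mosaics):
        diffs = []
        for units, _ in default_mosaics[:10]:
            individual = metrics_table(admitted(units))
            cum_alt = metrics_table(admitted(pool(units, by="altitude")))
            cum_month = metrics_table(admitted(pool(units, by="month")))
            report = individual_vs_cumulative(individual, cum_alt, cum_month)
            row = report[report["metric"] == "C"].iloc[0]
            diffs.append(row["mean_individual"]
                         - max(row["mean_cumulative_altitude"],
                               row["mean_cumulative_time"]))
        assert np.mean(diffs) > 0

    def test_identical_groups_flat(self):
        table = pd.DataFrame({"S": [4, 5, 6], "M": [8, 9, 10], "I": [3, 4, 5],
                              "L": [1, 1, 1.5], "C": [0.4, 0.5, 0.6],
                              "NODF": [0, 10, 20]})
        report = individual_vs_cumulative(table, table.copy(), table.copy())
        assert (report["p"] > 0.9).all()

    def test_connectance_size_relationship(self, default_mosaics):
        """Connectance declines with network size across pooling scales,
        mirroring the hyperbolic C ~ M relationship."""
        sizes, connectances = [], []
        for units, _ in default_mosaics[:6]:
            for table in (metrics_table(admitted(units)),
                          metrics_table(admitted(pool(units, by="altitude"))),
                          metrics_table(admitted(pool(units, by="all")))):
                sizes.extend(table["M"])
                connectances.extend(table["C"])
        rho = stats.spearmanr(sizes, connectances).statistic
        assert rho < 0
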