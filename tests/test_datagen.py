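"""The two synthetic study designs and their closed-form properties."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import measerr as me
from measerr.datagen import InvalidScenarioError


class TestAnalyticFormulas:
    @pytest.mark.parametrize(
        ("scenario", "expected"),
        [
            (me.LinearScenario(), 0.625),
            (me.LinearScenario(gamma=1), 0.71),
            (me.LinearScenario(gamma=4), 0.94),
            (me.LinearScenario(gamma=8), 0.98),
            (me.LogisticScenario(), 0.33),
            (me.LogisticScenario(gamma=0.01), 0.34),
            (me.LogisticScenario(gamma=0.1), 0.68),
            (me.LogisticScenario(gamma=0.2), 0.87),
        ],
    )
    def test_reliability_matches_design_values(self, scenario, expected):
        # agreement to the precision shown (half a unit in the last digit)
        assert me.reliability(scenario) == pytest.approx(expected, abs=0.005)

    def test_reliability_is_one_without_error(self):
        assert me.reliability(me.LinearScenario(tau2=0)) == 1.0

    @pytest.mark.parametrize(
        ("var", "tau2", "expected"),
        [(50, 30, 0.625), (50, 200, 0.2), (123.4, 0, 1.0)],
    )
    def test_attenuation_factor(self, var, tau2, expected):
        assert me.attenuation_factor(var, tau2) == pytest.approx(expected)

    def test_attenuation_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            me.attenuation_factor(0.0, 10.0)

    @given(
        var=st.floats(0.1, 1e3),
        tau2=st.floats(0.0, 1e3),
        delta=st.floats(0.01, 1e3),
    )
    def test_attenuation_strictly_decreasing_in_error_variance(
        self, var, tau2, delta
    ):
        assert me.attenuation_factor(var, tau2) > me.attenuation_factor(
            var, tau2 + delta
        )

    def test_attenuation_equals_reliability_iff_no_covariate_dependency(self):
        for tau2 in (5, 30, 200):
            s = me.LinearScenario(tau2=tau2, gamma=0)
            assert me.attenuation_factor(50.0, tau2) == pytest.approx(
                me.reliability(s)
            )
        # covariate dependency raises reliability but not the attenuation
        rels = []
        for gamma in (1, 4, 8):
            s = me.LinearScenario(gamma=gamma)
            assert me.attenuation_factor(50.0, s.tau2) == 0.625
            rels.append(me.reliability(s))
        assert rels == sorted(rels) and rels[0] > 0.625

    @pytest.mark.parametrize(
        ("gamma", "expected"), [(0, 0.2), (1, 0.2 + 5 / 75)]
    )
    def test_crude_effect_closed_form(self, gamma, expected):
        assert me.crude_effect(me.LinearScenario(gamma=gamma)) == pytest.approx(
            expected
        )

    def test_crude_effect_matches_large_sample_univariable_fit(self):
        # oracle: OLS of the outcome on the true exposure alone
        from measerr._fit import ols

        data = me.generate_linear(
            me.LinearScenario(gamma=1, n=200_000), seed=11
        )
        X = np.column_stack([np.ones(data.n), data.true_exposure])
        beta, cov = ols(X, data.outcome)
        se = np.sqrt(cov[1, 1])
        assert beta[1] == pytest.approx(0.2 + 5 / 75, abs=3 * se)

    def test_r_squared_reported_both_ways(self):
        base = me.LinearScenario()
        assert me.r_squared(base, "dgm") == pytest.approx(0.03, abs=0.005)
        assert me.r_squared(base, "alternative") == pytest.approx(30 / 130)
        # the alternative accounting maps the sigma2 grid to 0.6/0.86/0.75
        for sigma2, r2 in [(20, 0.6), (5, 0.857), (10, 0.75)]:
            s = me.LinearScenario(sigma2=sigma2)
            assert me.r_squared(s, "alternative") == pytest.approx(r2, abs=0.005)
        with pytest.raises(ValueError):
            me.r_squared(base, "nope")


class TestGenerators:
    def test_linear_shapes_and_roles(self, linear_data, linear_base):
        assert linear_data.n == linear_base.n
        assert linear_data.k == linear_base.k
        assert linear_data.n_covariates == 1
        assert linear_data.covariate_names == ("age",)
        assert linear_data.outcome_family == "linear"
        assert linear_data.true_exposure is not None

    def test_linear_error_variance_recovered(self, linear_data, linear_base):
        diffs = linear_data.exposure_replicates - linear_data.true_exposure[:, None]
        est = diffs.ravel().var(ddof=1)
        n_entries = diffs.size
        se = linear_base.tau2 * np.sqrt(2.0 / (n_entries - 1))
        assert est == pytest.approx(linear_base.tau2, abs=3 * se)

    def test_logistic_error_variance_recovered(self):
        scen = me.LogisticScenario()
        data = me.generate_logistic(scen, seed=5)
        diffs = data.exposure_replicates - data.true_exposure[:, None]
        est = diffs.ravel().var(ddof=1)
        se = scen.tau2 * np.sqrt(2.0 / (diffs.size - 1))
        assert est == pytest.approx(scen.tau2, abs=3 * se)

    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_zero_error_variance_gives_identical_replicates(self, family):
        if family == "linear":
            data = me.generate_linear(me.LinearScenario(tau2=0, n=50), seed=1)
        else:
            data = me.generate_logistic(me.LogisticScenario(tau2=0, n=50), seed=1)
        for j in range(data.k):
            np.testing.assert_array_equal(
                data.exposure_replicates[:, j], data.true_exposure
            )

    @pytest.mark.parametrize(("gamma", "var_x"), [(0, 50.0), (1, 75.0)])
    def test_marginal_exposure_variance(self, gamma, var_x):
        n = 100_000
        data = me.generate_linear(
            me.LinearScenario(gamma=gamma, n=n), seed=17
        )
        se = var_x * np.sqrt(2.0 / (n - 1))
        assert data.true_exposure.var(ddof=1) == pytest.approx(var_x, abs=3 * se)

    def test_logistic_base_empirical_reliability(self):
        data = me.generate_logistic(me.LogisticScenario(n=100_000), seed=19)
        ratio = data.true_exposure.var(ddof=1) / data.first_replicate.var(ddof=1)
        assert ratio == pytest.approx(1 / 3, abs=0.01)

    def test_logistic_outcome_model(self):
        data = me.generate_logistic(me.LogisticScenario(n=2000), seed=23)
        assert set(np.unique(data.outcome)) <= {0.0, 1.0}
        assert 0.05 < data.outcome.mean() < 0.5

    @pytest.mark.parametrize(
        "scenario",
        [s for s in me.scenario_grid("linear") + me.scenario_grid("logistic")],
        ids=lambda s: f"{s.family}-{s.label}",
    )
    def test_empirical_reliability_matches_formula_on_grid(self, scenario):
        n = 60_000
        big = dataclasses.replace(scenario, n=n)
        data = me.generate(big, seed=29)
        rel = me.reliability(scenario)
        est = data.true_exposure.var(ddof=1) / data.first_replicate.var(ddof=1)
        # delta-method scale for a ratio of variances, ~2*sqrt(2/n)
        assert est == pytest.approx(rel, abs=3 * 2 * np.sqrt(2.0 / n))

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(InvalidScenarioError):
            me.LinearScenario(n=1)
        with pytest.raises(InvalidScenarioError):
            me.LinearScenario(tau2=-1)
        with pytest.raises(InvalidScenarioError):
            me.LinearScenario(sigma2=0)
        with pytest.raises(InvalidScenarioError):
            me.LogisticScenario(k=0)

    def test_generate_dispatch_rejects_unknown(self):
        with pytest.raises(TypeError):
            me.generate(object(), seed=1)


class TestScenarioGrid:
    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_grid_size_and_base(self, family):
        grid = me.scenario_grid(family)
        assert len(grid) == 22
        assert grid[0].label == "base"
        labels = [s.label for s in grid]
        assert len(set(labels)) == 22

    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_one_factor_at_a_time(self, family):
        grid = me.scenario_grid(family)
        base = grid[0]
        for s in grid[1:]:
            diffs = [
                f.name
                for f in dataclasses.fields(s)
                if f.name != "label"
                and getattr(s, f.name) != getattr(base, f.name)
            ]
            assert len(diffs) == 1

    def test_published_grid_values(self):
        lin = {s.label for s in me.scenario_grid("linear")}
        assert {"tau2=200", "tau2=5", "n=125", "n=10000", "k=10",
                "sigma2=20", "gamma=8"} <= lin
        log = {s.label for s in me.scenario_grid("logistic")}
        assert {"tau2=0.1", "n=500", "k=10", "phi=0.2", "gamma=0.2"} <= log

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            me.scenario_grid("poisson")
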