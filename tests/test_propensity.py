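"""Propensity scores, IPTW/ATT weights, balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ordcausal import (
    PropensityConfig,
    PropensityModel,
    SimulationDesign,
    att_weights,
    effective_sample_size,
    fit_propensity,
    love_plot_table,
    simulate_dataset,
    smd,
    stabilized_weights,
)


@pytest.fixture(scope="module")
def scenario1_big():
    return simulate_dataset(SimulationDesign(1, 5000, 0.5, 1.0, seed=202))


class TestStabilizedWeights:
    def test_constant_propensity_gives_unit_weights(self):
        x = np.array([1, 0, 1, 0])
        w = stabilized_weights(np.full(4, 0.5), x)
        np.testing.assert_allclose(w, 1.0)

    def test_printed_formula(self):
        # p_x = 0.5, treated with pi = 0.25 -> w = 0.5 / 0.25 = 2
        w = stabilized_weights([0.25, 0.25], np.array([1, 0]), p_x=0.5)
        assert w[0] == pytest.approx(2.0)
        assert w[1] == pytest.approx(0.5 / 0.75)

    def test_rejects_boundary_propensities(self):
        with pytest.raises(ValueError):
            stabilized_weights([0.0, 0.5], np.array([0, 1]))

    def test_group_means_near_one_with_true_propensity(self, scenario1_big):
        d = scenario1_big
        w = stabilized_weights(np.clip(d.z, 1e-9, 1 - 1e-9), d.x)
        assert abs(w[d.x == 1].mean() - 1) < 0.05
        assert abs(w[d.x == 0].mean() - 1) < 0.05


class TestAttWeights:
    def test_treated_get_unit_weight(self):
        w = att_weights(np.array([0.3, 0.8, 0.9]), np.array([1, 1, 1]))
        np.testing.assert_allclose(w, 1.0)

    def test_controls_get_odds(self):
        w = att_weights(np.array([0.5, 0.8]), np.array([0, 0]))
        np.testing.assert_allclose(w, [1.0, 4.0])

    def test_certain_treatment_control_rejected(self):
        with pytest.raises(ValueError):
            att_weights(np.array([1.0]), np.array([0]))

    def test_att_reweights_controls_to_treated_distribution(
        self, scenario1_big
    ):
        d = scenario1_big
        pi = np.clip(d.z, 1e-9, 1 - 1e-9)
        w = att_weights(pi, d.x)
        treated_mean = d.z[d.x == 1].mean()
        ctrl = d.x == 0
        weighted_ctrl_mean = np.average(d.z[ctrl], weights=w[ctrl])
        assert abs(weighted_ctrl_mean - treated_mean) < 0.05


class TestSMD:
    def test_identical_groups_zero(self):
        v = np.tile([1.0, 2.0, 3.0], 2)
        x = np.repeat([1, 0], 3)
        assert smd(v, x) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_direct_arithmetic(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 200)
        x = (rng.random(200) < 0.5).astype(int)
        m1, m0 = v[x == 1].mean(), v[x == 0].mean()
        s1, s0 = v[x == 1].var(ddof=1), v[x == 0].var(ddof=1)
        expected = abs(m1 - m0) / np.sqrt((s1 + s0) / 2)
        assert smd(v, x) == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_paths(self):
        x = np.array([1, 1, 0, 0])
        assert smd(np.array([2.0, 2, 2, 2]), x) == 0.0
        with pytest.raises(ZeroDivisionError):
            smd(np.array([1.0, 1, 2, 2]), x)

    def test_categorical_returns_per_level_series(self):
        v = pd.Series(["a", "b", "a", "b", "a", "a"])
        x = np.array([1, 1, 1, 0, 0, 0])
        out = smd(v, x)
        assert set(out.index) == {"a", "b"}
        assert (out >= 0).all()

    def test_oracle_weighting_balances_the_confounder(self, scenario1_big):
        d = scenario1_big
        w = stabilized_weights(np.clip(d.z, 1e-9, 1 - 1e-9), d.x)
        assert smd(d.z, d.x) > 0.5  # confounded before weighting
        assert smd(d.z, d.x, weights=w) < 0.1

    def test_requires_both_groups(self):
        with pytest.raises(ValueError):
            smd(np.array([1.0, 2.0]), np.array([1, 1]))


class TestESS:
    def test_equal_weights_give_n(self):
        assert effective_sample_size(np.full(17, 3.2)) == pytest.approx(17)

    def test_kish_arithmetic(self):
        assert effective_sample_size([1, 1, 1, 3]) == pytest.approx(3.0)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size([])
        with pytest.raises(ValueError):
            effective_sample_size([1.0, 0.0])

    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=30))
    def test_bounded_by_n_with_equality_iff_constant(self, ws):
        w = np.asarray(ws)
        ess = effective_sample_size(w)
        assert 0 < ess <= len(w) + 1e-9
        if np.ptp(w) > 1e-6 * w.max():
            assert ess < len(w)


class TestFitPropensity:
    def test_no_signal_returns_marginal_rate(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(4000, 2))
        x = (rng.random(4000) < 0.4).astype(int)
        pi = fit_propensity(X, x, PropensityConfig(n_trees=50), seed=0)
        assert abs(pi.mean() - x.mean()) < 0.02
        assert pi.std() < 0.1

    @pytest.mark.parametrize("scenario", [1, 2])
    def test_binned_calibration_against_true_assignment(self, scenario):
        d = simulate_dataset(
            SimulationDesign(scenario, 5000, 0.5, 1.0, seed=64)
        )
        pi = fit_propensity(d.z, d.x, PropensityConfig(), seed=1)
        tau = d.z if scenario == 1 else d.z**2
        bins = np.clip((d.z * 10).astype(int), 0, 9)
        for b in range(1, 9):
            m = bins == b
            assert abs(pi[m].mean() - tau[m].mean()) < 0.08

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_propensity(np.random.rand(20, 1), np.ones(20, dtype=int))

    def test_constant_covariate_warns(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        x = (rng.random(200) < 0.5).astype(int)
        with pytest.warns(UserWarning, match="constant"):
            fit_propensity(X, x, PropensityConfig(n_trees=10), seed=0)

    def test_clip_bounds_respected(self):
        d = simulate_dataset(SimulationDesign(1, 2000, 0.5, 1.0, seed=2))
        cfg = PropensityConfig(clip=(0.1, 0.9))
        pi = fit_propensity(d.z, d.x, cfg, seed=0)
        assert pi.min() >= 0.1 and pi.max() <= 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PropensityConfig(n_trees=0)
        with pytest.raises(ValueError):
            PropensityConfig(learning_rate=1.5)
        with pytest.raises(ValueError):
            PropensityConfig(estimand="ATU")
        with pytest.raises(ValueError):
            PropensityConfig(clip=(0.5, 0.2))
        with pytest.raises(ValueError):
            PropensityConfig(stop_method="ks.max")


class TestLovePlot:
    def test_rows_ordered_by_unweighted_smd(self):
        before = pd.Series({"a": 0.5, "b": 0.9})
        after = pd.Series({"a": 0.05, "b": 0.1})
        tab = love_plot_table(before, after)
        assert list(tab["covariate"]) == ["b", "b", "a", "a"]
        assert list(tab["phase"]) == ["unweighted", "weighted"] * 2

    def test_empty_covariate_set(self):
        tab = love_plot_table(pd.Series(dtype=float), pd.Series(dtype=float))
        assert tab.empty

    def test_mismatched_covariates_rejected(self):
        with pytest.raises(ValueError):
            love_plot_table(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


class TestPropensityModel:
    def test_end_to_end_att_on_survey(self, tiny_survey):
        covs = ["perceived_risk", "conspiracy", "education"]
        cfg = PropensityConfig(n_trees=40, learning_rate=0.15, estimand="ATT",
                               sampling_weights_used=True)
        res = PropensityModel(
            tiny_survey, "vaccinated", covs, cfg,
            sampling_weights="sampling_weight",
        ).fit(seed=0)
        treated = tiny_survey["vaccinated"].to_numpy() == 1
        np.testing.assert_allclose(res.weights[treated], 1.0)
        assert np.all(res.weights > 0) and np.all(np.isfinite(res.weights))
        assert res.ess_by_group[1] <= res.ess_before_by_group[1] + 1e-9
        assert set(res.smd_table.index) == set(covs)
        # weighting should improve balance for most covariates here
        improved = (res.smd_after <= res.smd_before + 0.05).mean()
        assert improved >= 2 / 3
        assert "ESS" in res.summary()
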