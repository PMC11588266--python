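"""Weighted cumulative-logit model: likelihood, CIs, recode, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from ordcausal import (
    ConvergenceError,
    CumulativeLogitModel,
    EffectEstimate,
    SimulationDesign,
    bootstrap_or_ci,
    derive_intercepts,
    recode_outcome,
    simulate_dataset,
)


def _grid_search_loglik(y, x, step_coarse=0.1, step_fine=0.004):
    """Brute-force maximum of the 3-category cumulative-logit likelihood
    over (alpha1, alpha2, beta), independent of the fitting code."""

    def loglik(a1, a2, b):
        # minus convention: P(Y<=j) = expit(alpha_j - b*x)
        c1 = expit(a1 - b * x)
        c2 = expit(a2 - b * x)
        p = np.choose(y - 1, [c1, c2 - c1, 1.0 - c2])
        return np.sum(np.log(np.clip(p, 1e-300, None)))

    def scan(a1s, ds, bs):
        best = (-np.inf, None)
        for a1 in a1s:
            for d in ds:
                for b in bs:
                    ll = loglik(a1, a1 + d, b)
                    if ll > best[0]:
                        best = (ll, (a1, d, b))
        return best

    ll, (a1, d, b) = scan(
        np.arange(-3, 3, step_coarse),
        np.arange(step_coarse, 5, step_coarse),
        np.arange(-3, 3, step_coarse),
    )
    ll, _ = scan(
        np.arange(a1 - 0.12, a1 + 0.12, step_fine),
        np.arange(max(d - 0.12, step_fine), d + 0.12, step_fine),
        np.arange(b - 0.12, b + 0.12, step_fine),
    )
    return ll


@pytest.fixture(scope="module")
def confounded_fit(scenario1_dataset):
    d = scenario1_dataset
    X = np.column_stack([d.x, d.z])
    return CumulativeLogitModel(d.y, X, exog_names=["x", "z"]).fit()


class TestLikelihood:
    def test_unit_weights_equal_unweighted(self, scenario1_dataset):
        d = scenario1_dataset
        X = np.column_stack([d.x, d.z])
        res_u = CumulativeLogitModel(d.y, X, exog_names=["x", "z"]).fit()
        res_w = CumulativeLogitModel(
            d.y, X, weights=np.ones(len(d)), exog_names=["x", "z"]
        ).fit()
        np.testing.assert_allclose(
            res_u.params.to_numpy(), res_w.params.to_numpy(), atol=1e-6
        )

    def test_weight_rescaling_leaves_estimates_unchanged(
        self, scenario1_dataset
    ):
        d = scenario1_dataset
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2.0, len(d))
        X = d.x[:, None]
        res1 = CumulativeLogitModel(d.y, X, weights=w).fit()
        res2 = CumulativeLogitModel(d.y, X, weights=7.3 * w).fit()
        np.testing.assert_allclose(
            res1.params.to_numpy(), res2.params.to_numpy(), atol=1e-5
        )

    def test_intercept_only_thresholds_are_empirical_cumulative_logits(self):
        counts = (15, 20, 30, 20, 15)
        y = np.repeat(np.arange(1, 6), counts)
        res = CumulativeLogitModel(y).fit()
        expected = derive_intercepts(np.asarray(counts) / 100)
        np.testing.assert_allclose(res.thresholds, expected, atol=1e-5)

    def test_loglik_matches_grid_search_oracle(self):
        y = np.array([1, 1, 2, 2, 3, 3, 1, 2, 3, 3, 2, 1])
        x = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        res = CumulativeLogitModel(y, x[:, None]).fit()
        oracle = _grid_search_loglik(y, x)
        assert res.llf >= oracle - 1e-3
        assert abs(res.llf - oracle) < 1e-3

    def test_matches_reference_ordinal_implementation(self):
        sm_ord = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        d = simulate_dataset(SimulationDesign(1, 800, 0.5, 1.0, seed=17))
        X = pd.DataFrame({"x": d.x, "z": d.z})
        mine = CumulativeLogitModel(d.y, X).fit()
        ref = sm_ord.OrderedModel(d.y, X, distr="logit").fit(
            method="bfgs", disp=0
        )
        np.testing.assert_allclose(mine.llf, ref.llf, rtol=1e-6)
        np.testing.assert_allclose(
            mine.slopes.to_numpy(), ref.params.iloc[:2].to_numpy(), atol=1e-4
        )

    def test_loglik_history_nondecreasing(self, scenario1_dataset):
        d = scenario1_dataset
        res = CumulativeLogitModel(d.y, d.x[:, None]).fit(track_history=True)
        hist = np.asarray(res.llf_history)
        assert len(hist) > 1
        assert np.all(np.diff(hist) >= -1e-9)

    def test_warm_start_reaches_same_optimum(self, confounded_fit,
                                             scenario1_dataset):
        d = scenario1_dataset
        X = np.column_stack([d.x, d.z])
        warm = CumulativeLogitModel(d.y, X, exog_names=["x", "z"]).fit(
            start_params=confounded_fit.params.to_numpy()
        )
        np.testing.assert_allclose(warm.llf, confounded_fit.llf, atol=1e-6)

    def test_requires_two_observed_categories(self):
        with pytest.raises(ValueError):
            CumulativeLogitModel(np.ones(10, dtype=int))

    def test_unobserved_intermediate_category_warns(self):
        y = np.array([1, 1, 3, 3, 1, 3, 1, 3])
        with pytest.warns(UserWarning, match="collapsed"):
            CumulativeLogitModel(y)


class TestInference:
    def test_wald_ci_matches_normal_quantile_formula(self, confounded_fit):
        est = confounded_fit.wald_ci("x")
        b = confounded_fit.slopes["x"]
        se = confounded_fit.bse["x"]
        assert est.or_point == pytest.approx(np.exp(b))
        assert est.ci_low == pytest.approx(np.exp(b - 1.959964 * se), rel=1e-5)
        assert est.ci_high == pytest.approx(np.exp(b + 1.959964 * se), rel=1e-5)
        assert est.ci_low <= est.or_point <= est.ci_high

    def test_or_is_exp_of_slope_exactly(self, confounded_fit):
        est = confounded_fit.wald_ci("x")
        assert est.or_point == float(np.exp(confounded_fit.slopes["x"]))

    def test_covariance_symmetric_psd(self, confounded_fit):
        cov = confounded_fit.cov_params().to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)

    def test_wald_requires_convergence(self, confounded_fit):
        import copy

        broken = copy.copy(confounded_fit)
        broken.converged = False
        with pytest.raises(ConvergenceError):
            broken.wald_ci("x")

    def test_unknown_term_raises(self, confounded_fit):
        with pytest.raises(KeyError):
            confounded_fit.wald_ci("nope")

    def test_effect_estimate_wald_must_bracket(self):
        with pytest.raises(ValueError):
            EffectEstimate("x", 1.5, 1.6, 2.0, "wald")

    def test_summary_mentions_convergence_and_or(self, confounded_fit):
        text = confounded_fit.summary()
        assert "converged: True" in text
        assert "OR" in text


class TestRecodeOutcome:
    def test_collapse_rule(self):
        np.testing.assert_array_equal(
            recode_outcome(np.arange(1, 8)), [1, 1, 1, 2, 3, 4, 5]
        )

    @pytest.mark.parametrize("bad", [[0], [8], [1, 9]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            recode_outcome(np.asarray(bad))

    @given(st.lists(st.integers(1, 7), min_size=2, max_size=20))
    def test_order_preserving(self, ys):
        y = np.sort(np.asarray(ys))
        r = recode_outcome(y)
        assert np.all(np.diff(r) >= 0)
        assert r.min() >= 1 and r.max() <= 5


class TestBootstrap:
    def test_rejects_invalid_replication_count(self):
        df = pd.DataFrame({"v": [1.0, 2.0]})
        with pytest.raises(ValueError):
            bootstrap_or_ci(df, lambda d, r: 0.0, n_boot=0)

    def test_degenerate_estimator_gives_zero_width(self):
        df = pd.DataFrame({"v": np.arange(10.0)})
        est = bootstrap_or_ci(df, lambda d, r: 0.3, n_boot=25, seed=1)
        assert est.ci_low == est.ci_high == pytest.approx(np.exp(0.3))

    def test_failure_fraction_guard(self):
        df = pd.DataFrame({"v": np.arange(10.0)})

        def flaky(d, rng):
            if d["v"].iloc[0] != 0:  # fails for most resamples
                raise RuntimeError("boom")
            return 0.0

        with pytest.raises(RuntimeError):
            bootstrap_or_ci(df, flaky, n_boot=30, seed=2)

    def test_ci_brackets_point_for_smooth_statistic(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"v": rng.normal(0.4, 1.0, 300)})
        est = bootstrap_or_ci(
            df, lambda d, r: float(d["v"].mean()), n_boot=200, seed=5
        )
        assert est.ci_low < est.or_point < est.ci_high
        assert est.ci_method == "bootstrap"
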