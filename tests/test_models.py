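import math

import numpy as np
import pandas as pd
import pytest

import elevpart as ep
from elevpart import models


class TestAicc:
    def test_direct_arithmetic(self):
        # loglik=0, k=2, n=73 -> 2k + 2k(k+1)/(n-k-1) = 4 + 12/70
        assert ep.aicc(0.0, 2, 73) == pytest.approx(4 + 12 / 70)

    def test_large_n_limit_is_aic(self):
        ll, k = -120.0, 4
        assert ep.aicc(ll, k, 10**7) == pytest.approx(-2 * ll + 2 * k, rel=1e-6)

    def test_equal_inputs_equal_outputs(self):
        assert ep.aicc(-5.0, 3, 40) == ep.aicc(-5.0, 3, 40)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ep.aicc(0.0, 5, 6)


class TestAkaikeWeights:
    def test_two_equal_models(self):
        assert np.allclose(ep.akaike_weights([100.0, 100.0]), [0.5, 0.5])

    def test_delta_19_33(self):
        # matches a null-model weight of 0.00 at 2 d.p. in a candidate table
        w = ep.akaike_weights([0.0, 19.33])
        assert w[1] == pytest.approx(math.exp(-19.33 / 2) / (1 + math.exp(-19.33 / 2)))
        assert w[1] == pytest.approx(6.3e-5, rel=0.02)
        assert round(w[0], 2) == 1.0

    def test_single_model(self):
        assert np.allclose(ep.akaike_weights([42.0]), [1.0])

    def test_sum_one_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(100, 600, size=9)
        w = ep.akaike_weights(a)
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w, ep.akaike_weights(a + 123.4))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ep.akaike_weights([])


class TestVif:
    def test_orthogonal_predictors(self):
        n = 40
        x1 = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        x2 = np.tile([1.0, -1.0], n // 2)
        v = ep.vif(pd.DataFrame({"a": x1, "b": x2}))
        assert v["a"] == pytest.approx(1.0) and v["b"] == pytest.approx(1.0)

    def test_correlation_0_9_closed_form(self):
        # construct exact sample correlation 0.9 -> VIF = 1/(1-0.81)
        rng = np.random.default_rng(1)
        x1 = rng.standard_normal(200)
        e = rng.standard_normal(200)
        x1 = (x1 - x1.mean()) / x1.std(ddof=1)
        e = e - e.mean()
        e -= (e @ x1) / (x1 @ x1) * x1  # orthogonalize
        e /= e.std(ddof=1)
        x2 = 0.9 * x1 + math.sqrt(1 - 0.81) * e
        v = ep.vif(pd.DataFrame({"a": x1, "b": x2}))
        assert v["a"] == pytest.approx(1 / (1 - 0.81), rel=1e-6)

    def test_duplicated_column_flagged_infinite(self):
        x = np.arange(10.0)
        v = ep.vif(pd.DataFrame({"a": x, "b": x}))
        assert math.isinf(v["a"]) and math.isinf(v["b"])

    def test_single_predictor_is_one(self):
        assert ep.vif(pd.DataFrame({"a": np.arange(5.0)})) == {"a": 1.0}


class TestPolynomial:
    def test_quadratic_truth_recovered(self):
        # AICc occasionally admits a spurious higher term (its known mild
        # overfit rate), so recovery is asserted across seeds: the quadratic
        # wins the majority and the true curvature is never missed
        elev = np.linspace(900, 2300, 73)
        z = (elev - elev.mean()) / elev.std()
        picks = []
        for s in range(20):
            rng = np.random.default_rng(s)
            y = 12 + 3 * z - 5 * z**2 + 0.4 * rng.standard_normal(73)
            best, _ = ep.fit_polynomial(y, elev, max_degree=4)
            picks.append(best)
        assert all(p >= 2 for p in picks)
        assert sum(p == 2 for p in picks) >= 12

    def test_constant_richness_selects_intercept_only(self):
        best, _ = ep.fit_polynomial(np.full(30, 7.0), np.linspace(0, 1, 30))
        assert best == 0

    def test_constant_elevation_rejected(self):
        with pytest.raises(ValueError):
            ep.fit_polynomial(np.arange(20.0), np.full(20, 5.0))

    def test_curve_evaluates_fit(self):
        elev = np.linspace(0, 10, 40)
        y = 1.0 + 2.0 * elev
        _, fits = ep.fit_polynomial(y, elev, max_degree=2)
        curve = models.polynomial_curve(fits[1], elev)
        assert np.allclose(curve, y, atol=1e-8)


def _synthetic_comparison(seed=0, placement="mde_uniform", **kw):
    truth = ep.study_like_preset(seed=seed)
    truth.placement = placement
    for k, v in kw.items():
        setattr(truth, k, v)
    occ, cov, _, _ = ep.generate(truth, include_specimens=False)
    from elevpart import mde

    curve = mde.analytic_expected_richness(
        mde.compute_ranges(occ), mde.Domain(occ.n_sites)
    )
    X = models.prepare_predictors(cov, mde_curve=curve)
    return occ.site_richness(), X


class TestCompareCandidates:
    def test_mde_truth_recovered(self):
        rich, X = _synthetic_comparison(seed=1, mean_range_size=20)
        comp = ep.compare_candidates(rich, X)
        assert comp.best == "MDE"
        assert comp.table["weight"].sum() == pytest.approx(1.0)
        assert comp.table["delta_aicc"].min() == 0.0

    def test_all_noise_keeps_null_competitive(self):
        rng = np.random.default_rng(2)
        _, X = _synthetic_comparison(seed=2)
        noise = rng.standard_normal(len(X))
        comp = ep.compare_candidates(noise, X)
        null_aicc = comp.table.set_index("model").loc["null", "aicc"]
        assert null_aicc - comp.table["aicc"].min() < 6.0

    def test_shuffled_richness_calibration(self):
        rich, X = _synthetic_comparison(seed=3, mean_range_size=20)
        rng = np.random.default_rng(3)
        null_w = []
        for _ in range(20):
            comp = ep.compare_candidates(rng.permutation(rich), X)
            null_w.append(
                float(comp.table.set_index("model").loc["null", "weight"])
            )
        assert np.mean(null_w) > 0.05  # null stays in play on destroyed signal

    def test_nonpositive_covariate_named_in_error(self):
        cov = pd.DataFrame(
            {"vt_count": [1, 0, 2], "ct_count": [1, 1, 1], "sr": [1.0, 1, 1],
             "ap": [1.0, 1, 1], "at": [1.0, 1, 1], "ws": [1.0, 1, 1]},
            index=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="VT"):
            models.prepare_predictors(cov)

    def test_importance_sums_weights_over_models(self):
        rich, X = _synthetic_comparison(seed=4)
        comp = ep.compare_candidates(rich, X)
        w = comp.table.set_index("model")["weight"]
        expected_ct = w.get("CT", 0.0) + w.get("CT+VT", 0.0)
        assert comp.importance["CT"] == pytest.approx(float(expected_ct))


class TestForwardStepwise:
    def test_single_informative_variable(self):
        rng = np.random.default_rng(5)
        n = 73
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        y = 5 + 3 * X["b"] + 0.5 * rng.standard_normal(n)
        res = ep.forward_stepwise(y, X, standardize=False)
        assert res.entry_order[0] == "b"
        assert len(res.entry_order) <= 2  # noise rarely follows, never more

    def test_zero_variables_returns_null(self):
        y = np.arange(10.0)
        res = ep.forward_stepwise(y, pd.DataFrame(index=range(10)))
        assert res.entry_order == [] and res.final.predictors == ()

    def test_final_adjusted_r2_not_below_first_step(self):
        rich, X = _synthetic_comparison(seed=6, placement="mixed",
                                        mean_range_size=20, covariate_effect=3.0)
        res = ep.forward_stepwise(rich, X)
        assert len(res.entry_order) >= 1
        first = res.steps.iloc[0]["adj_r2_total"]
        assert res.final.adj_r2 >= first - 1e-12


class TestCoefficientIntervals:
    def test_band_matches_analytic_confidence_band(self):
        rng = np.random.default_rng(9)
        n = 60
        x = np.linspace(-2, 2, n)
        y = 1.0 + 2.0 * x + rng.standard_normal(n)
        X = pd.DataFrame({"x": x})
        fit = models.fit_gaussian(y, X)
        lo, hi = models.simulate_coefficient_intervals(fit, X, n_draws=20000, seed=4)
        # closed-form oracle: t-based confidence band for the mean
        import scipy.stats as st

        Xd = np.column_stack([np.ones(n), x])
        H = Xd @ np.linalg.inv(Xd.T @ Xd) @ Xd.T
        res = y - H @ y
        s2 = res @ res / (n - 2)
        se = np.sqrt(s2 * np.diag(H))
        tcrit = st.t.ppf(0.975, n - 2)
        width_analytic = 2 * tcrit * se
        width_sim = hi - lo
        assert np.all(np.abs(width_sim - width_analytic) / width_analytic < 0.05)

    def test_fixed_seed_identical(self):
        x = np.linspace(0, 1, 30)
        y = x * 2 + 0.1 * np.sin(x * 9)
        X = pd.DataFrame({"x": x})
        fit = models.fit_gaussian(y, X)
        b1 = models.simulate_coefficient_intervals(fit, X, n_draws=500, seed=7)
        b2 = models.simulate_coefficient_intervals(fit, X, n_draws=500, seed=7)
        assert np.array_equal(b1[0], b2[0]) and np.array_equal(b1[1], b2[1])

    def test_vanishing_noise_shrinks_band(self):
        x = np.linspace(0, 1, 40)
        X = pd.DataFrame({"x": x})
        rng = np.random.default_rng(1)
        widths = []
        for scale in (1.0, 0.01):
            y = 3 * x + scale * rng.standard_normal(40)
            fit = models.fit_gaussian(y, X)
            lo, hi = models.simulate_coefficient_intervals(fit, X, n_draws=2000, seed=1)
            widths.append(np.mean(hi - lo))
        assert widths[1] < widths[0] / 20
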