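import warnings

import numpy as np
import pytest

import bifacet as bf
from bifacet.estimation import HeywoodWarning, significance
from bifacet.moments import SampleMoments


def _closed_form_two_indicator(matrix):
    cov = matrix[1, 0]
    return {
        "phi[F,F]": cov,
        "theta[Y1,Y1]": matrix[0, 0] - cov,
        "theta[Y2,Y2]": matrix[1, 1] - cov,
    }


class TestFit:
    def test_two_indicator_model_matches_closed_form(self, two_indicator_config):
        model = bf.build_model(two_indicator_config)
        S = np.array([[2.0, 1.2], [1.2, 1.8]])
        moments = SampleMoments(["Y1", "Y2"], S, 100)
        res = bf.fit(model, moments)
        oracle = _closed_form_two_indicator(S)
        for lab, want in oracle.items():
            assert res.theta.get(lab) == pytest.approx(want, abs=1e-8)
        assert res.discrepancy == pytest.approx(0.0, abs=1e-12)

    def test_self_consistency_at_known_theta(self, moments):
        model = bf.make_model("fig2b")
        res = bf.fit(model, moments)
        implied = res.implied.matrix
        synth = SampleMoments(model.var_names, implied, moments.n,
                              {v.name: v.scale for v in model.variables})
        res2 = bf.fit(model, synth)
        assert res2.discrepancy == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res2.theta.values, res.theta.values, atol=1e-6)

    def test_first_order_an_math_correlation(self, first_order_fit):
        sol = bf.standardize(first_order_fit)
        assert sol.factor_corr.loc["AN", "Math"] == pytest.approx(0.400, abs=0.03)

    def test_df_of_reported_fits(self, moments):
        expected = {("fig1a_equal", None): 11, ("fig1b_equal_fix_s", None): 21,
                    ("fig1b_equal_fix_g", None): 17, ("fig1b_free_g", None): 10,
                    ("fig2b", None): 15, ("fig3b", "AN"): 15,
                    ("fig1b_free_g_fix_g", None): 12}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for (key, ref), df in expected.items():
                res = bf.fit(bf.make_model(key, ref), moments)
                assert res.df == df, key

    def test_s1_fit_equals_first_order_fit(self, first_order_fit, s1_fit_an):
        assert s1_fit_an.discrepancy == pytest.approx(
            first_order_fit.discrepancy, abs=1e-8)
        assert np.allclose(s1_fit_an.implied.matrix, first_order_fit.implied.matrix,
                           atol=1e-6)

    def test_regression_fit_equals_covariance_fit(self, first_order_fit,
                                                  first_order_regression_fit):
        assert first_order_regression_fit.discrepancy == pytest.approx(
            first_order_fit.discrepancy, abs=1e-8)

    def test_statistic_is_n_minus_one_times_discrepancy(self, first_order_fit):
        assert first_order_fit.statistic == pytest.approx(
            218 * first_order_fit.discrepancy)

    def test_heywood_case_warns_not_errors(self):
        cfg = {
            "mode": "measurement-only",
            "variables": [
                {"name": "Y1", "role": "indicator", "facet": "F"},
                {"name": "Y2", "role": "indicator", "facet": "F"},
            ],
            "factors": [{"name": "F", "kind": "facet", "scaling": "one-loading-fixed"}],
            "loadings": [
                {"var": "Y1", "factor": "F", "status": "fixed", "value": 1.0},
                {"var": "Y2", "factor": "F", "status": "fixed", "value": 1.0},
            ],
        }
        model = bf.build_model(cfg)
        # covariance exceeds a variance -> negative error variance estimate
        S = np.array([[1.0, 1.4], [1.4, 2.2]])
        moments = SampleMoments(["Y1", "Y2"], S, 80)
        with pytest.warns(HeywoodWarning):
            res = bf.fit(model, moments)
        assert res.converged
        assert any("Heywood" in w for w in res.warnings)

    def test_dwls_requires_weights(self, moments):
        with pytest.raises(ValueError, match="weight"):
            bf.fit(bf.make_model("fig2b"), moments, estimator="DWLS")

    def test_ml_estimator_runs(self, two_indicator_config):
        model = bf.build_model(two_indicator_config)
        S = np.array([[2.0, 1.2], [1.2, 1.8]])
        moments = SampleMoments(["Y1", "Y2"], S, 100)
        res = bf.fit(model, moments, estimator="ML")
        # saturated structure: ML and ULS agree at the exact solution
        assert res.theta.get("phi[F,F]") == pytest.approx(1.2, abs=1e-5)


class TestStandardize:
    def test_perfect_indicator_has_unit_loading_and_reliability(self):
        cfg = {
            "mode": "measurement-only",
            "variables": [
                {"name": "Y1", "role": "indicator", "facet": "F"},
                {"name": "Y2", "role": "indicator", "facet": "F"},
            ],
            "factors": [{"name": "F", "kind": "facet", "scaling": "variance-fixed"}],
            "loadings": [
                {"var": "Y1", "factor": "F", "status": "fixed", "value": 1.0},
                {"var": "Y2", "factor": "F", "status": "fixed", "value": 1.0},
            ],
        }
        model = bf.build_model(cfg)
        res = bf.fit(model, SampleMoments(["Y1", "Y2"], np.array([[1.0, 1.0], [1.0, 1.0]]), 50))
        sol = bf.standardize(res)
        assert sol.loadings.loc["Y1", "F"] == pytest.approx(1.0)
        assert sol.reliability["Y1"] == pytest.approx(1.0)

    def test_table5_bs_consistency(self, first_order_regression_fit):
        # b_s = b * SD(predictor) / SD(criterion); criterion SD is 1
        sol = bf.standardize(first_order_regression_fit)
        b = first_order_regression_fit.theta.get("beta[Math,AN]")
        sd_an = np.sqrt(first_order_regression_fit.theta.get("phi[AN,AN]"))
        assert sol.regressions.loc["Math", "AN"] == pytest.approx(b * sd_an, abs=1e-10)
        assert sol.regressions.loc["Math", "AN"] == pytest.approx(0.239, abs=0.03)

    def test_zero_criterion_covariances_standardize_to_zero(self, moments):
        model = bf.make_model("fig2b")
        res = bf.fit(model, moments)
        theta = res.theta.with_updates(
            {lab: 0.0 for lab in res.theta.labels
             if lab.startswith("phi[") and ("Math" in lab or "Eng" in lab)
             and not ("Math" in lab and "Eng" in lab)})
        res.theta = theta
        res.implied = bf.implied_covariance(model, theta)
        sol = bf.standardize(res)
        for f in ("NS", "AN", "UN"):
            assert sol.factor_corr.loc[f, "Math"] == 0.0
            assert sol.factor_corr.loc[f, "Eng"] == 0.0

    def test_reliabilities_match_printed_range(self, first_order_fit):
        sol = bf.standardize(first_order_fit)
        printed = {"NS1": 0.789, "NS2": 0.785, "AN1": 0.651, "AN2": 0.724,
                   "UN1": 0.712, "UN2": 0.664}
        for name, want in printed.items():
            assert sol.reliability[name] == pytest.approx(want, abs=0.03)


class TestRSquared:
    def test_first_order_regression_r2(self, first_order_regression_fit):
        r2 = bf.rsquared(first_order_regression_fit)
        assert r2["Math"] == pytest.approx(0.233, abs=0.03)
        assert r2["Eng"] == pytest.approx(0.106, abs=0.03)

    def test_zero_betas_give_zero_r2(self, first_order_regression_fit):
        model = first_order_regression_fit.model
        theta = first_order_regression_fit.theta.with_updates(
            {lab: 0.0 for lab in model.slot_labels if lab.startswith("beta")})
        res = bf.fit(model, first_order_regression_fit.moments, start=theta)
        theta0 = res.theta.with_updates(
            {lab: 0.0 for lab in model.slot_labels if lab.startswith("beta")})
        res.theta = theta0
        res.implied = bf.implied_covariance(model, theta0)
        assert np.allclose(bf.rsquared(res).to_numpy(), 0.0)

    def test_covariance_mode_has_no_r2(self, first_order_fit):
        with pytest.raises(ValueError, match="regression"):
            bf.rsquared(first_order_fit)

    def test_s1_regression_r2_equals_first_order(self, first_order_regression_fit,
                                                 s1_regression_fit_an):
        r2a = bf.rsquared(first_order_regression_fit)
        r2b = bf.rsquared(s1_regression_fit_an)
        assert r2a["Math"] == pytest.approx(r2b["Math"], abs=1e-8)
        assert r2a["Eng"] == pytest.approx(r2b["Eng"], abs=1e-8)


class TestStandardErrors:
    def test_free_g_criterion_parameters_all_nonsignificant(self, free_g_fit):
        bf.standard_errors(free_g_fit)
        sig = significance(free_g_fit)
        rows = [i for i in sig.index if i.startswith("phi[")
                and ("Math" in i or "Eng" in i) and not ("Math" in i and "Eng" in i)]
        assert len(rows) == 8
        assert not sig.loc[rows, "significant"].any()

    def test_fixing_specific_covariances_halves_g_math_se(self, moments, free_g_fit):
        bf.standard_errors(free_g_fit)
        se_free = significance(free_g_fit).loc["phi[Math,G]", "se"]
        res = bf.fit(bf.make_model("fig1b_free_g_fix_s"), moments)
        bf.standard_errors(res)
        se_fixed = significance(res).loc["phi[Math,G]", "se"]
        assert se_fixed < 0.5 * se_free

    def test_equal_loading_extended_bifactor_raises_not_identified(self, moments):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = bf.fit(bf.make_model("fig1b_equal"), moments)
        with pytest.raises(bf.NotIdentifiedError, match="not locally identified"):
            bf.standard_errors(res)
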