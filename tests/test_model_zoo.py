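import numpy as np
import pytest

import bifacet as bf
from bifacet.model_spec import ModelSpecError
from bifacet.model_zoo import composite_from_regression, s1_part_correlations


class TestCatalog:
    def test_s1_requires_reference_facet(self):
        with pytest.raises(ModelSpecError, match="reference"):
            bf.make_model("fig3b")

    def test_unknown_key_rejected(self):
        with pytest.raises(ModelSpecError, match="unknown catalog key"):
            bf.make_model("fig9z")

    def test_ref_suffix_parsing(self):
        model = bf.make_model("fig3b_refAN")
        assert "AN" in model.factor_names
        assert "AN-S" not in model.factor_names

    def test_s1_an_reference_has_19_free_and_df_15(self):
        model = bf.make_model("fig3b", "AN")
        assert model.n_free == 19
        assert model.n_moments - model.n_free == 15

    def test_swapping_reference_facet_keeps_fit(self, moments, s1_fit_an):
        res_ns = bf.fit(bf.make_model("fig3b", "NS"), moments)
        assert res_ns.discrepancy == pytest.approx(s1_fit_an.discrepancy, abs=1e-8)
        assert res_ns.df == s1_fit_an.df
        # labeled estimates differ: the reference factor changes meaning
        assert set(res_ns.theta.labels) != set(s1_fit_an.theta.labels)

    def test_swapping_reference_keeps_r2(self, moments, s1_regression_fit_an):
        res_ns = bf.fit(bf.make_model("fig3c", "NS"), moments)
        r2a = bf.rsquared(s1_regression_fit_an)
        r2b = bf.rsquared(res_ns)
        assert np.allclose(r2a.to_numpy(), r2b.to_numpy(), atol=1e-8)


class TestReferenceFacetInvariances:
    def test_reference_coefficient_equals_simple_regression(self, moments,
                                                            s1_regression_fit_an):
        # simple regression of Math on the AN facet alone: b = Cov(AN,Math)/Var(AN)
        cfg_vars = [
            {"name": "AN1", "role": "indicator", "facet": "AN"},
            {"name": "AN2", "role": "indicator", "facet": "AN"},
            {"name": "Math", "role": "criterion", "scale": "latent-response"},
            {"name": "Eng", "role": "criterion", "scale": "latent-response"},
        ]
        cfg = {
            "mode": "regression",
            "variables": cfg_vars,
            "factors": [{"name": "AN", "kind": "facet", "scaling": "one-loading-fixed"}],
            "loadings": [
                {"var": "AN1", "factor": "AN", "status": "fixed", "value": 1.0},
                {"var": "AN2", "factor": "AN", "status": "fixed", "value": 1.0},
            ],
            "regressions": [{"factor": "AN", "criterion": c, "status": "free"}
                            for c in ("Math", "Eng")],
            "residual_covs": [{"row": "Math", "col": "Eng", "status": "free"}],
        }
        simple = bf.fit(bf.build_model(cfg), moments.subset(["AN1", "AN2", "Math", "Eng"]))
        for crit in ("Math", "Eng"):
            assert s1_regression_fit_an.theta.get(f"beta[{crit},AN]") == pytest.approx(
                simple.theta.get(f"beta[{crit},AN]"), abs=1e-6)

    def test_nonreference_coefficients_match_first_order_regression(
            self, first_order_regression_fit, s1_regression_fit_an):
        # NS and UN rows agree between the two regression tables
        for crit in ("Math", "Eng"):
            for facet in ("NS", "UN"):
                b_first = first_order_regression_fit.theta.get(f"beta[{crit},{facet}]")
                b_s1 = s1_regression_fit_an.theta.get(f"beta[{crit},{facet}-S]")
                assert b_s1 == pytest.approx(b_first, abs=1e-6)


class TestComposite:
    def test_math_composite_correlation_is_sqrt_r2(self, first_order_regression_fit):
        comp = composite_from_regression(first_order_regression_fit, "Math")
        r2 = bf.rsquared(first_order_regression_fit)["Math"]
        assert comp.correlation == pytest.approx(np.sqrt(r2), abs=1e-10)
        assert comp.correlation == pytest.approx(np.sqrt(0.233), abs=0.03)
        assert set(comp.weights) == {"NS", "AN", "UN"}

    def test_degenerate_composite_flagged(self, first_order_regression_fit):
        res = first_order_regression_fit
        theta0 = res.theta.with_updates(
            {lab: 0.0 for lab in res.theta.labels if lab.startswith("beta")})
        frozen = bf.fit(res.model, res.moments, start=theta0)
        frozen.theta = theta0
        frozen.implied = bf.implied_covariance(res.model, theta0)
        comp = composite_from_regression(frozen, "Math")
        assert comp.degenerate
        assert comp.correlation == 0.0

    def test_english_composite_dominated_by_an(self, first_order_regression_fit,
                                               moments):
        comp = composite_from_regression(first_order_regression_fit, "Eng")
        bf.standard_errors(first_order_regression_fit)
        from bifacet.estimation import significance

        sig = significance(first_order_regression_fit)
        assert abs(comp.weights["AN"]) > abs(comp.weights["NS"])
        assert abs(comp.weights["AN"]) > abs(comp.weights["UN"])
        assert sig.loc["beta[Eng,AN]", "significant"]
        assert not sig.loc["beta[Eng,NS]", "significant"]
        assert not sig.loc["beta[Eng,UN]", "significant"]

    def test_requires_regression_fit(self, first_order_fit):
        with pytest.raises(ValueError, match="regression"):
            composite_from_regression(first_order_fit, "Math")


class TestS1PartCorrelations:
    def test_reference_correlations_match_first_order(self, first_order_fit, s1_fit_an):
        table = s1_part_correlations(s1_fit_an)
        sol_first = bf.standardize(first_order_fit)
        ref = table[table["kind"] == "zero-order"].set_index("criterion")
        for crit in ("Math", "Eng"):
            assert ref.loc[crit, "correlation"] == pytest.approx(
                sol_first.factor_corr.loc["AN", crit], abs=1e-6)

    def test_specific_english_correlations_nonsignificant(self, s1_fit_an):
        bf.standard_errors(s1_fit_an)
        from bifacet.estimation import significance

        sig = significance(s1_fit_an)
        assert not sig.loc["phi[Eng,NS-S]", "significant"]
        assert not sig.loc["phi[Eng,UN-S]", "significant"]
        # while the Math part correlations are significant
        assert sig.loc["phi[Math,NS-S]", "significant"]
        assert sig.loc["phi[Math,UN-S]", "significant"]

    def test_orthogonal_population_gives_zero_part_correlations(self):
        model = bf.make_model("fig3b", "AN")
        theta = model.default_theta().with_updates({
            "phi[AN,AN]": 1.5, "phi[NS-S,NS-S]": 1.2, "phi[UN-S,UN-S]": 1.3,
            "phi[Math,AN]": 0.4, "phi[Eng,AN]": 0.3, "phi[Eng,Math]": 0.35,
        })
        implied = bf.implied_covariance(model, theta)
        from bifacet.moments import SampleMoments

        synth = SampleMoments(model.var_names, implied.matrix, 1000,
                              {v.name: v.scale for v in model.variables})
        res = bf.fit(model, synth)
        table = s1_part_correlations(res)
        parts = table[table["kind"] == "part"]["correlation"]
        assert np.allclose(parts.to_numpy(), 0.0, atol=1e-6)

    def test_rejects_non_s1_models(self, first_order_fit):
        with pytest.raises(ValueError, match="reference"):
            s1_part_correlations(first_order_fit)
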