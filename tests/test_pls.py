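import numpy as np
import pandas as pd
import pytest

from conftest import simulate_two_construct, two_construct_model
from satsem.model_spec import (LatentVariable, ModelDefinition,
                               StructuralPath, default_initial_model)
from satsem.pls import (PLSSEM, bootstrap, effects_decomposition, mga_compare,
                        min_sample_inverse_sqrt, pls_estimate,
                        structural_from_correlations)
from satsem.reference import (STRUCTURAL_PATHS, latent_correlation_frame)
from satsem.synthetic import GeneratorConfig, SurveyDataset, simulate_survey


class TestSampleSizeRule:
    def test_published_minimum(self):
        assert min_sample_inverse_sqrt(0.11) == 511

    def test_with_attrition_and_groups(self):
        assert min_sample_inverse_sqrt(0.11, attrition=0.20, n_groups=2) == 1278

    def test_strictly_greater_boundary(self):
        # (2.486/2.486)^2 = 1 -> smallest integer strictly greater is 2
        assert min_sample_inverse_sqrt(2.486) == 2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_sample_inverse_sqrt(0.0)
        with pytest.raises(ValueError):
            min_sample_inverse_sqrt(0.2, attrition=1.0)


class TestCoreEstimation:
    def test_perfectly_correlated_indicators(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        df = pd.DataFrame({"a0": x, "a1": 2 * x + 1})
        m = ModelDefinition(
            latents=[LatentVariable("A", "exogenous", ("a0", "a1"))], paths=[])
        fit = PLSSEM(df, m).fit()
        w = {k: v for k, (c, v) in fit.outer_weights.items()}
        assert w["a0"] == pytest.approx(w["a1"], rel=1e-6)
        assert np.allclose(fit.outer_loadings["A"], 1.0, atol=1e-10)

    def test_two_construct_recovery(self):
        df = simulate_two_construct(beta=0.6, n=5000, seed=2,
                                    n_items=(3, 3), loading=0.95)
        fit = PLSSEM(df, two_construct_model(n_items=(3, 3))).fit()
        assert fit.path_coefficients[("A", "B")] == pytest.approx(0.6, abs=0.05)
        assert fit.converged

    def test_single_indicator_equals_ols_oracle(self):
        """With one indicator per construct PLS collapses to OLS path
        analysis on the standardized items."""
        rng = np.random.default_rng(3)
        n = 400
        a = rng.standard_normal(n)
        b = 0.5 * a + rng.standard_normal(n)
        c = 0.4 * a - 0.3 * b + rng.standard_normal(n)
        df = pd.DataFrame({"xa": a, "xb": b, "xc": c})
        m = ModelDefinition(
            latents=[LatentVariable("A", "exogenous", ("xa",)),
                     LatentVariable("B", "endogenous", ("xb",)),
                     LatentVariable("C", "endogenous", ("xc",))],
            paths=[StructuralPath("A", "B"), StructuralPath("A", "C"),
                   StructuralPath("B", "C", -1)])
        fit = PLSSEM(df, m).fit()
        z = (df - df.mean()) / df.std(ddof=1)
        bhat_b = np.linalg.lstsq(z[["xa"]], z["xb"], rcond=None)[0]
        bhat_c = np.linalg.lstsq(z[["xa", "xb"]], z["xc"], rcond=None)[0]
        assert fit.path_coefficients[("A", "B")] == pytest.approx(
            float(bhat_b[0]), abs=1e-8)
        assert fit.path_coefficients[("A", "C")] == pytest.approx(
            float(bhat_c[0]), abs=1e-8)
        assert fit.path_coefficients[("B", "C")] == pytest.approx(
            float(bhat_c[1]), abs=1e-8)

    def test_latent_scores_standardized(self, survey_small, draft_model):
        fit = pls_estimate(survey_small, draft_model)
        s = fit.latent_scores
        assert np.allclose(s.mean(), 0.0, atol=1e-8)
        assert np.allclose(s.std(ddof=1), 1.0, atol=1e-8)

    def test_loadings_are_item_score_correlations(self, survey_small,
                                                  draft_model):
        fit = pls_estimate(survey_small, draft_model)
        z = fit.item_data["PV1"]
        assert fit.outer_loadings.loc["PV1", "PV"] == pytest.approx(
            float(np.corrcoef(z, fit.latent_scores["PV"])[0, 1]), abs=1e-10)

    def test_affine_rescaling_invariance(self, survey_small, draft_model):
        fit1 = pls_estimate(survey_small, draft_model)
        scaled = survey_small.responses * 3.0 + 7.0
        fit2 = PLSSEM(scaled, draft_model).fit()
        for p, v in fit1.path_coefficients.items():
            assert fit2.path_coefficients[p] == pytest.approx(v, abs=1e-8)

    def test_internal_consistency_with_correlation_solver(self, survey_small,
                                                          draft_model):
        fit = pls_estimate(survey_small, draft_model)
        beta, _ = structural_from_correlations(
            fit.latent_correlations, paths=fit.structural_paths)
        for p, v in fit.path_coefficients.items():
            assert beta[p] == pytest.approx(v, abs=1e-10)

    def test_hoc_methods_agree_roughly(self, survey_small, draft_model):
        f1 = pls_estimate(survey_small, draft_model, hoc_method="two_stage")
        f2 = pls_estimate(survey_small, draft_model,
                          hoc_method="repeated_indicators")
        for p in [("PQ", "PV"), ("PQ", "PS"), ("PS", "PT")]:
            assert f1.path_coefficients[p] == pytest.approx(
                f2.path_coefficients[p], abs=0.05)

    def test_zero_variance_item_rejected(self, draft_model):
        d = simulate_survey(GeneratorConfig(n_respondents=100, seed=5),
                            draft_model)
        d.responses["PV1"] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            PLSSEM(d.responses, draft_model).fit()


class TestStructuralFromCorrelations:
    def test_published_correlations_reproduce_coefficients(self):
        R = latent_correlation_frame()
        beta, r2 = structural_from_correlations(R, paths=STRUCTURAL_PATHS)
        assert beta[("PE", "PS")] == pytest.approx(0.070, abs=5e-4)
        assert beta[("PQ", "PS")] == pytest.approx(0.421, abs=0.01)
        assert beta[("PV", "PS")] == pytest.approx(0.467, abs=0.01)

    def test_single_predictor_equals_correlation(self):
        R = latent_correlation_frame()
        beta, _ = structural_from_correlations(R, paths=[("PS", "PT")])
        assert beta[("PS", "PT")] == pytest.approx(R.loc["PS", "PT"])

    def test_identity_correlations_pass_through(self):
        R = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        R.loc["a", "c"] = R.loc["c", "a"] = 0.4
        beta, _ = structural_from_correlations(
            R, paths=[("a", "c"), ("b", "c")])
        assert beta[("a", "c")] == pytest.approx(0.4)
        assert beta[("b", "c")] == pytest.approx(0.0)

    def test_normal_equation_identity(self):
        """Predicted correlations R_pp @ beta reproduce the observed
        predictor-target correlations."""
        R = latent_correlation_frame()
        preds = ["PE", "PQ", "PV"]
        beta, _ = structural_from_correlations(
            R, paths=[(p, "PS") for p in preds])
        b = np.array([beta[(p, "PS")] for p in preds])
        assert np.allclose(R.loc[preds, preds].to_numpy() @ b,
                           R.loc[preds, "PS"].to_numpy(), atol=1e-12)

    def test_singular_block_rejected(self):
        R = pd.DataFrame(np.ones((3, 3)), index=list("abc"),
                         columns=list("abc"))
        with pytest.raises(ValueError, match="singular"):
            structural_from_correlations(R, paths=[("a", "c"), ("b", "c")])


class TestEffects:
    def test_published_total_effect(self):
        beta = {("PQ", "PS"): 0.421, ("PQ", "PV"): 0.676, ("PV", "PS"): 0.467}
        eff = effects_decomposition(beta)
        assert eff.loc[("PQ", "PS"), "total"] == pytest.approx(0.737, abs=5e-4)

    def test_no_indirect_chain(self):
        eff = effects_decomposition({("a", "b"): 0.3})
        assert eff.loc[("a", "b"), "total"] == pytest.approx(0.3)
        assert eff.loc[("a", "b"), "indirect"] == 0.0

    def test_chain_product(self):
        eff = effects_decomposition({("a", "b"): 0.5, ("b", "c"): 0.5})
        assert eff.loc[("a", "c"), "total"] == pytest.approx(0.25)
        assert eff.loc[("a", "c"), "direct"] == 0.0

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            effects_decomposition({("a", "b"): 0.5, ("b", "a"): 0.5})


class TestBootstrap:
    def test_deterministic_under_seed(self):
        df = simulate_two_construct(beta=0.5, n=150, seed=6)
        model = PLSSEM(df, two_construct_model())
        b1 = bootstrap(model, n_resamples=25, seed=9)
        b2 = bootstrap(model, n_resamples=25, seed=9)
        assert b1.estimates.equals(b2.estimates)

    def test_ci_ordering_and_strong_path_excludes_zero(self):
        df = simulate_two_construct(beta=0.6, n=1000, seed=7)
        model = PLSSEM(df, two_construct_model())
        bs = bootstrap(model, n_resamples=300, seed=1)
        row = bs.estimates.loc[("A", "B")]
        assert row["ci_low"] <= row["coefficient"] <= row["ci_high"]
        assert row["ci_low"] > 0
        assert row["p"] < 0.001

    def test_se_matches_resample_spread(self):
        df = simulate_two_construct(beta=0.4, n=300, seed=8)
        model = PLSSEM(df, two_construct_model())
        bs = bootstrap(model, n_resamples=200, seed=2)
        assert bs.estimates.loc[("A", "B"), "se"] == pytest.approx(
            bs.draws[("A", "B")].std(ddof=1))


class TestMga:
    @staticmethod
    def grouped_dataset(beta1, beta2, n, seed):
        df1 = simulate_two_construct(beta1, n, seed, n_items=(2, 2))
        df2 = simulate_two_construct(beta2, n, seed + 1, n_items=(2, 2))
        resp = pd.concat([df1, df2], ignore_index=True)
        group = pd.Series(["g1"] * n + ["g2"] * n, name="group")
        return SurveyDataset(responses=resp, group=group, scale=(-100, 100))

    def test_identical_groups_no_difference(self):
        df = simulate_two_construct(0.5, 300, 10, n_items=(2, 2))
        resp = pd.concat([df, df], ignore_index=True)
        d = SurveyDataset(responses=resp,
                          group=pd.Series(["a"] * 300 + ["b"] * 300),
                          scale=(-100, 100))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mga_compare(d, two_construct_model(n_items=(2, 2)),
                              n_resamples=100, seed=3)
        assert res.loc[("A", "B"), "difference"] == pytest.approx(0.0)
        assert res.loc[("A", "B"), "p_value"] > 0.5

    def test_distinct_groups_detected(self):
        d = self.grouped_dataset(0.3, 0.7, n=1000, seed=11)
        res = mga_compare(d, two_construct_model(n_items=(2, 2)),
                          n_resamples=200, seed=4)
        assert res.loc[("A", "B"), "p_value"] < 0.05
        assert abs(res.loc[("A", "B"), "difference"]) > 0.2

    def test_reproducible(self):
        d = self.grouped_dataset(0.4, 0.6, n=600, seed=12)
        r1 = mga_compare(d, two_construct_model(n_items=(2, 2)),
                         n_resamples=50, seed=5)
        r2 = mga_compare(d, two_construct_model(n_items=(2, 2)),
                         n_resamples=50, seed=5)
        assert r1.equals(r2)

    def test_missing_group_rejected(self):
        d = self.grouped_dataset(0.4, 0.6, n=100, seed=13)
        import warnings
        with pytest.raises(ValueError, match="missing"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mga_compare(d, two_construct_model(n_items=(2, 2)),
                        groups=["g1", "zz"], n_resamples=10, seed=1)


class TestSecondOrderReporting:
    def test_derived_quality_path_is_facet_chain_total(self, survey_small,
                                                       draft_model):
        fit = pls_estimate(survey_small, draft_model)
        total = 0.0
        for f in draft_model.hoc_components["PQ"]:
            total += fit.path_coefficients[("PE", f)] \
                * fit.path_coefficients[(f, "PQ")]
        assert fit.hoc_derived[("PE", "PQ")] == pytest.approx(total, abs=1e-10)

    def test_quality_determined_by_facets(self, survey_small, draft_model):
        fit = pls_estimate(survey_small, draft_model)
        assert fit.r_squared["PQ"] > 0.99

    def test_hypothesis_sign_consistency(self, survey_small, draft_model):
        fit = pls_estimate(survey_small, draft_model)
        signs = fit.hypothesis_signs()
        assert signs["consistent"].all()
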