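import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from satsem.model_spec import LatentVariable, ModelDefinition
from satsem.screening import (alpha_if_deleted, cronbach_alpha, ctt_flag_table,
                              efa_flags, extreme_group_ttest, floor_ceiling,
                              item_correlations, stepwise_flags,
                              stepwise_select, total_scores)
from satsem.synthetic import SurveyDataset


def tiny_dataset(columns, scale=(1, 10), group=None):
    return SurveyDataset(responses=pd.DataFrame(columns, dtype=float),
                         group=group, scale=scale)


def flat_model(items, name="D"):
    return ModelDefinition(
        latents=[LatentVariable(name, "exogenous", tuple(items))], paths=[])


class TestFloorCeiling:
    def test_all_at_maximum(self):
        d = tiny_dataset({"x": [10] * 10, "y": [5] * 10})
        fl, ce, ffl, fce = floor_ceiling(d, "x")
        assert (fl, ce, ffl, fce) == (0.0, 1.0, False, True)

    def test_uniform_responses_unflagged(self):
        d = tiny_dataset({"x": list(range(1, 11)) * 10})
        fl, ce, ffl, fce = floor_ceiling(d, "x")
        assert fl == ce == pytest.approx(0.10)
        assert not ffl and not fce

    def test_strict_20_percent_boundary(self):
        d = tiny_dataset({"x": [1] * 19 + [5] * 81})
        assert floor_ceiling(d, "x")[2] is False
        d = tiny_dataset({"x": [1] * 20 + [5] * 80})
        assert floor_ceiling(d, "x")[2] is True

    def test_proportions_partition_unity(self, survey_small):
        for it in ["PT1", "PQ6"]:
            col = survey_small.responses[it].dropna()
            fl, ce, *_ = floor_ceiling(survey_small, it)
            interior = ((col > 1) & (col < 10)).mean()
            assert fl + ce + interior == pytest.approx(1.0)


class TestExtremeGroupTtest:
    def test_item_equal_to_total_discriminates(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 11, size=200)
        d = tiny_dataset({"x": x})
        t, p, flag, note = extreme_group_ttest(d, "x", totals=pd.Series(x))
        assert p < 1e-10 and not flag

    def test_noise_item_flagged(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            totals = pd.Series(rng.normal(size=500))
            d = tiny_dataset({"x": rng.integers(1, 11, size=500)})
            _t, _p, flag, _ = extreme_group_ttest(d, "x", totals=totals)
            hits += flag
        assert hits >= 16  # ~95% of seeds

    def test_welch_statistic_matches_hand_computation(self):
        # totals force bottom-3 = [2,2,4], top-3 = [8,9,10] (27% of 10 -> 3)
        item = [2, 2, 4, 5, 5, 6, 6, 8, 9, 10]
        totals = pd.Series(range(10), dtype=float)
        d = tiny_dataset({"x": item})
        t, p, flag, _ = extreme_group_ttest(d, "x", totals=totals)
        low, high = np.array([2, 2, 4]), np.array([8, 9, 10])
        se = np.sqrt(low.var(ddof=1) / 3 + high.var(ddof=1) / 3)
        assert t == pytest.approx((high.mean() - low.mean()) / se)
        assert not flag

    def test_degenerate_groups_flagged(self):
        d = tiny_dataset({"x": [5] * 20})
        t, p, flag, note = extreme_group_ttest(
            d, "x", totals=pd.Series(range(20), dtype=float))
        assert flag and note == "degenerate"


class TestItemCorrelations:
    def test_single_item_dimension_self_inclusive(self):
        d = tiny_dataset({"x": [1, 3, 5, 7, 9], "y": [2, 2, 4, 6, 9]})
        m = ModelDefinition(latents=[
            LatentVariable("A", "exogenous", ("x",)),
            LatentVariable("B", "exogenous", ("y",))], paths=[])
        r_dim, _r_tot, dflag, _ = item_correlations(d, "x", m)
        assert r_dim == 1.0 and dflag is False

    def test_duplicate_item_unflagged(self):
        d = tiny_dataset({"x": [1, 3, 5, 7, 9], "y": [1, 3, 5, 7, 9]})
        m = flat_model(["x", "y"])
        r_dim, r_tot, dflag, tflag = item_correlations(d, "x", m)
        assert r_dim == pytest.approx(1.0)
        assert not dflag and not tflag

    def test_pearson_matches_hand_formula(self):
        x = np.array([1.0, 4, 2, 8, 5])
        y = np.array([2.0, 5, 1, 9, 7])
        d = tiny_dataset({"x": x, "y": y})
        m = flat_model(["x", "y"])
        r_dim, _, _, _ = item_correlations(d, "x", m)
        tot = x + y
        num = np.sum((x - x.mean()) * (tot - tot.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((tot - tot.mean()) ** 2))
        assert r_dim == pytest.approx(num / den)

    def test_zero_variance_item_rejected(self):
        d = tiny_dataset({"x": [5, 5, 5, 5], "y": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="zero variance"):
            item_correlations(d, "x", flat_model(["x", "y"]))


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [3.0, 4, 5, 6]})
        assert cronbach_alpha(df) == pytest.approx(1.0)

    @pytest.mark.parametrize("k,r", [(2, 0.5), (4, 0.3), (3, 0.7)])
    def test_spearman_brown_closed_form(self, k, r):
        rng = np.random.default_rng(17)
        n = 40000
        f = rng.standard_normal(n)
        X = np.sqrt(r) * f[:, None] + np.sqrt(1 - r) * rng.standard_normal((n, k))
        alpha = cronbach_alpha(pd.DataFrame(X))
        assert alpha == pytest.approx(k * r / (1 + (k - 1) * r), abs=0.015)

    def test_trust_scale_alpha_near_published(self):
        # two items correlated 0.6287 give alpha = 2r/(1+r) ~ 0.772
        r = 0.772 / (2 - 0.772)
        rng = np.random.default_rng(23)
        n = 60000
        f = rng.standard_normal(n)
        X = np.sqrt(r) * f[:, None] + np.sqrt(1 - r) * rng.standard_normal((n, 2))
        assert cronbach_alpha(pd.DataFrame(X)) == pytest.approx(0.772, abs=0.01)

    @given(arrays(np.float64, (12, 4), elements=st.floats(-5, 5)))
    @settings(max_examples=40, deadline=None)
    def test_matches_covariance_matrix_formula(self, X):
        df = pd.DataFrame(X)
        S = np.cov(X, rowvar=False)
        if S.trace() == 0 or abs(S.sum()) < 1e-8 * S.trace():
            return
        k = X.shape[1]
        expected = k / (k - 1) * (1 - S.trace() / S.sum())
        assert cronbach_alpha(df) == pytest.approx(expected, rel=1e-9)

    def test_alpha_if_deleted_flags_bad_item(self):
        rng = np.random.default_rng(5)
        n = 2000
        f = rng.standard_normal(n)
        good = 0.85 * f[:, None] + 0.5 * rng.standard_normal((n, 3))
        noise = rng.standard_normal((n, 1))
        d = tiny_dataset(
            pd.DataFrame(np.clip(np.round(5 + 1.5 * np.hstack([good, noise])),
                                 1, 10),
                         columns=["g1", "g2", "g3", "junk"]))
        m = flat_model(["g1", "g2", "g3", "junk"])
        tab = alpha_if_deleted(d, m)
        assert tab.loc["junk", "alpha_flag"]
        assert not tab.loc["g1", "alpha_flag"]

    def test_two_item_dimension_not_applicable(self, survey_small, draft_model):
        tab = alpha_if_deleted(survey_small, draft_model)
        assert tab.loc["PV1", "alpha_flag"] is None
        assert tab.loc["PS1", "alpha_flag"] is not None


class TestStepwise:
    def test_single_item_dimension_kept(self, survey_small, draft_model):
        flags = stepwise_flags(survey_small, draft_model)
        assert not flags["PQ1"]  # only item of the overall-quality facet

    def test_noise_candidate_flagged(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 500
            f = rng.standard_normal(n)
            strong = 0.9 * f[:, None] + 0.4 * rng.standard_normal((n, 3))
            noise = rng.standard_normal((n, 1))
            X = pd.DataFrame(np.hstack([strong, noise]),
                             columns=["s1", "s2", "s3", "junk"])
            y = total_scores(SurveyDataset(
                X[["s1", "s2", "s3"]], scale=(-100, 100)))
            chosen = stepwise_select(y, X)
            hits += "junk" not in chosen
        assert hits >= 9

    def test_identical_items_tie_broken_by_order(self):
        x = np.array([1.0, 5, 2, 8, 4, 6, 3, 9, 7, 2])
        d = tiny_dataset({"x1": x, "x2": x, "x3": x})
        m = flat_model(["x1", "x2", "x3"])
        flags = stepwise_flags(d, m)
        assert not flags["x1"] and flags["x2"] and flags["x3"]


class TestEfa:
    @staticmethod
    def two_factor_data(n=3000, loading=0.8, seed=6, extra_noise_item=False):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((n, 2))
        err = np.sqrt(1 - loading**2)
        cols = {}
        for j in range(3):
            cols[f"a{j}"] = loading * f[:, 0] + err * rng.standard_normal(n)
            cols[f"b{j}"] = loading * f[:, 1] + err * rng.standard_normal(n)
        if extra_noise_item:
            cols["junk"] = rng.standard_normal(n)
        return pd.DataFrame(cols)

    def test_two_orthogonal_factors_recovered(self):
        df = self.two_factor_data()
        items = list(df.columns)
        d = tiny_dataset(df, scale=(-100, 100))
        m = ModelDefinition(latents=[
            LatentVariable("A", "exogenous", ("a0", "a1", "a2")),
            LatentVariable("B", "exogenous", ("b0", "b1", "b2"))], paths=[])
        tab = efa_flags(d, m, n_factors=2)
        assert not any(tab.loc[i, "efa_flag"] for i in items)
        assert np.allclose(tab["max_loading"], 0.8, atol=0.06)

    def test_pure_noise_item_flagged(self):
        df = self.two_factor_data(extra_noise_item=True)
        d = tiny_dataset(df, scale=(-100, 100))
        m = ModelDefinition(latents=[
            LatentVariable("A", "exogenous", ("a0", "a1", "a2")),
            LatentVariable("B", "exogenous", ("b0", "b1", "b2", "junk"))],
            paths=[])
        tab = efa_flags(d, m, n_factors=2)
        assert tab.loc["junk", "efa_flag"]

    def test_single_factor_loadings_are_root_communalities(self):
        df = self.two_factor_data()[["a0", "a1", "a2"]]
        d = tiny_dataset(df, scale=(-100, 100))
        m = flat_model(["a0", "a1", "a2"])
        tab = efa_flags(d, m, n_factors=1)
        assert np.allclose(tab["max_loading"], 0.8, atol=0.06)


class TestFlagTableInvariance:
    def test_respondent_order_invariance(self, survey_small, draft_model):
        tab1 = ctt_flag_table(survey_small, draft_model)
        rng = np.random.default_rng(99)
        perm = rng.permutation(survey_small.n_respondents)
        shuffled = survey_small.subset(perm)
        tab2 = ctt_flag_table(shuffled, draft_model)
        flag_cols = [c for c in tab1.columns if c.endswith("_flag")]
        assert tab1[flag_cols].equals(tab2[flag_cols])
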