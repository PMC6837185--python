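"""Model selection, averaging, LRT, clustering, group comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sealdive.stats import (
    all_subsets_aicc,
    collinearity_screen,
    group_compare,
    lrt_nested,
    model_average,
    standardize_and_cluster,
)
from sealdive.synthetic import pelagic_archetype, simulate_population


@pytest.fixture(scope="module")
def regression_data():
    rng = np.random.default_rng(1)
    n = 30
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    y = 1.0 + 2.0 * X["a"] + rng.normal(size=n)
    return y, X


class TestCollinearity:
    def test_perfect_collinearity_excluded(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=50)
        df = pd.DataFrame({"x1": x1, "x2": 2 * x1, "x3": rng.normal(size=50)})
        retained, log = collinearity_screen(df, keep=["x1"])
        assert "x2" not in retained
        assert "x1" in retained and "x3" in retained
        assert log[0][0] == "x2" and log[0][1] == "x1"

    def test_orthogonal_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        retained, log = collinearity_screen(df)
        assert retained == ["a", "b", "c"]
        assert log == []

    def test_matches_brute_force_correlation_matrix(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=100)
        df = pd.DataFrame(
            {
                "u": base + rng.normal(0, 0.1, 100),  # r(u, v) > 0.7
                "v": base,
                "w": rng.normal(size=100),
            }
        )
        corr = df.corr().abs()
        retained, log = collinearity_screen(df)
        # greedy order: u kept first, v clashes with u iff |r| > 0.7
        assert ("v" not in retained) == (corr.loc["u", "v"] > 0.7)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(ValueError):
            collinearity_screen(df)


class TestAICc:
    def test_three_predictors_eight_models(self, regression_data):
        y, X = regression_data
        assert len(all_subsets_aicc(y, X).models) == 8

    def test_small_sample_correction_term(self):
        # k = 3, n = 20: AICc - AIC = 2*3*4/(20-3-1) = 1.5
        from sealdive.stats import aicc_from_loglik

        ll = -10.0
        aic = -2 * ll + 2 * 3
        assert aicc_from_loglik(ll, 3, 20) - aic == pytest.approx(1.5)

    def test_ranking_matches_statsmodels_refit(self, regression_data):
        """Independent oracle: refit every subset with statsmodels OLS."""
        import statsmodels.api as sm

        y, X = regression_data
        ms = all_subsets_aicc(y, X)
        n = len(y)
        oracle = {}
        for r in range(4):
            for terms in itertools.combinations(X.columns, r):
                exog = sm.add_constant(X[list(terms)]) if terms else np.ones((n, 1))
                fit = sm.OLS(y, exog).fit()
                k = len(terms) + 2
                aic = -2 * fit.llf + 2 * k
                oracle[terms] = aic + 2 * k * (k + 1) / (n - k - 1)
        for m in ms.models:
            assert m.aicc == pytest.approx(oracle[m.terms], rel=1e-9)
        want_order = sorted(oracle, key=oracle.get)
        assert [m.terms for m in ms.models] == want_order


class TestModelAverage:
    def test_single_retained_model_equals_its_ols(self, regression_data):
        y, X = regression_data
        ms = all_subsets_aicc(y, X)
        avg = model_average(ms, delta_max=0.0)
        best = ms.models[0]
        for term in best.terms:
            assert avg.loc[term, "estimate"] == pytest.approx(best.params[term])
            assert avg.loc[term, "relative_importance"] == pytest.approx(1.0)

    def test_two_model_weights(self):
        deltas = np.array([0.0, 2.0])
        w = np.exp(-deltas / 2)
        w = w / w.sum()
        assert w == pytest.approx([0.731, 0.269], abs=5e-4)

    def test_weights_sum_to_one_and_shift_invariant(self, regression_data):
        y, X = regression_data
        ms = all_subsets_aicc(y, X)
        table = ms.table()
        assert table["weight"].sum() == pytest.approx(1.0)
        for m in ms.models:
            m.aicc += 100.0  # common shift
        shifted = ms.table()
        assert np.allclose(shifted["weight"], table["weight"])

    def test_term_in_all_models_has_importance_one(self, regression_data):
        y, X = regression_data
        avg = model_average(all_subsets_aicc(y, X), delta_max=4.0)
        assert avg.loc["a", "relative_importance"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_substitution_full_average(self, regression_data):
        """Averaged coefficient equals the weight-weighted sum with zeros
        where a term is absent — checked by explicit enumeration."""
        y, X = regression_data
        ms = all_subsets_aicc(y, X)
        retained = [m for m in ms.models if m.aicc - ms.models[0].aicc <= 4.0]
        w = np.exp(-np.array([m.aicc - ms.models[0].aicc for m in retained]) / 2)
        w /= w.sum()
        avg = model_average(ms, delta_max=4.0)
        for term in ["b", "c"]:
            manual = sum(wi * float(m.params.get(term, 0.0)) for wi, m in zip(w, retained))
            assert avg.loc[term, "estimate"] == pytest.approx(manual)


class TestLRT:
    def test_identical_models_statistic_zero(self, regression_data):
        y, X = regression_data
        stat, p, df = lrt_nested(y, X[["a"]], X[["a"]])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_matches_explicit_gaussian_loglik(self, regression_data):
        from sealdive.stats import gaussian_loglik, _ols_fit

        y, X = regression_data
        n = len(y)
        stat, _, _ = lrt_nested(y, X[["a"]], X[["a", "b"]])
        Xs = np.column_stack([np.ones(n), X[["a"]].to_numpy()])
        Xl = np.column_stack([np.ones(n), X[["a", "b"]].to_numpy()])
        _, _, rss_s = _ols_fit(y.to_numpy(), Xs)
        _, _, rss_l = _ols_fit(y.to_numpy(), Xl)
        want = 2 * (gaussian_loglik(rss_l, n) - gaussian_loglik(rss_s, n))
        assert stat == pytest.approx(want, rel=1e-9)

    def test_type_one_error_near_nominal(self):
        """Adding a pure-noise predictor rejects at ~5 % under the null."""
        rng = np.random.default_rng(0)
        n, reps, alpha = 40, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            z = rng.normal(size=n)  # irrelevant
            y = 1 + x + rng.normal(size=n)
            df_s = pd.DataFrame({"x": x})
            df_l = pd.DataFrame({"x": x, "z": z})
            _, p, _ = lrt_nested(y, df_s, df_l)
            rejections += p < alpha
        rate = rejections / reps
        assert 0.03 <= rate <= 0.08

    def test_non_nested_rejected(self, regression_data):
        y, X = regression_data
        with pytest.raises(ValueError):
            lrt_nested(y, X[["a"]], X[["b", "c"]])


class TestClustering:
    def test_standardized_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(1, 10, size=(6, 4)), columns=list("abcd"))
        res = standardize_and_cluster(df)
        assert np.allclose(res.standardized.sum(axis=0), 1.0)

    def test_identical_seals_merge_at_height_zero(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 2.0, 9.0]})
        res = standardize_and_cluster(df)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_strategy_population_recovered(self):
        """The 25/7 pelagic/benthic split is recovered exactly (ARI = 1)."""
        from sklearn.metrics import adjusted_rand_score

        summaries, labels = simulate_population(25, 7, seed=5)
        res = standardize_and_cluster(summaries)
        assert adjusted_rand_score(labels, res.memberships) == pytest.approx(1.0)
        sizes = sorted(res.memberships.value_counts().tolist())
        assert sizes == [7, 25]

    def test_no_signal_population_at_chance(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = pelagic_archetype()
        summaries, labels = simulate_population(5, 5, configs=(cfg, cfg), seed=1)
        res = standardize_and_cluster(summaries)
        assert adjusted_rand_score(labels, res.memberships) < 0.5

    def test_row_order_invariance(self):
        summaries, _ = simulate_population(6, 3, seed=2)
        res1 = standardize_and_cluster(summaries)
        shuffled = summaries.sample(frac=1.0, random_state=0)
        res2 = standardize_and_cluster(shuffled)
        m1 = res1.memberships
        m2 = res2.memberships.loc[m1.index]
        # same partition up to label swap
        agree = (m1 == m2).all() or (m1 != m2).all()
        assert agree

    def test_merge_heights_non_decreasing(self):
        summaries, _ = simulate_population(6, 3, seed=2)
        heights = standardize_and_cluster(summaries).linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_distance_matrix_properties(self):
        summaries, _ = simulate_population(4, 2, seed=3)
        res = standardize_and_cluster(summaries)
        D = res.distances.to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_rejections(self):
        with pytest.raises(ValueError):
            standardize_and_cluster(pd.DataFrame({"a": [1.0]}))
        with pytest.raises(ValueError):
            standardize_and_cluster(pd.DataFrame({"a": [1.0, -1.0], "b": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            standardize_and_cluster(pd.DataFrame({"a": [np.nan, 1.0], "b": [1.0, 2.0]}))


class TestGroupCompare:
    def test_mannwhitney_exact_small_sample(self):
        res = group_compare([1, 2, 3], [4, 5, 6], test="mannwhitney", alternative="less")
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(0.05)

    def test_mannwhitney_matches_full_enumeration(self):
        """Exact p equals the permutation proportion over all C(8, 4)
        rank assignments."""
        a = [1.2, 3.4, 2.2, 0.5]
        b = [4.1, 5.0, 3.9, 6.2]
        res = group_compare(a, b, test="mannwhitney", alternative="less")
        pooled = np.array(a + b)
        ranks = sps.rankdata(pooled)
        n_a = len(a)
        u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
        count = 0
        total = 0
        for idx in itertools.combinations(range(len(pooled)), n_a):
            u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
            count += u <= u_obs
            total += 1
        assert res["p"] == pytest.approx(count / total, rel=1e-9)

    def test_identical_groups_anova_f_zero(self):
        res = group_compare([1, 2, 3], [1, 2, 3], test="anova")
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_three_group_anova(self):
        rng = np.random.default_rng(0)
        g = [rng.normal(size=10) for _ in range(3)]
        res = group_compare(*g, test="anova")
        want = sps.f_oneway(*g)
        assert res["F"] == pytest.approx(float(want.statistic))

    def test_monotone_spearman(self):
        res = group_compare([1, 2, 3, 4], [10, 20, 30, 40], test="spearman")
        assert res["rho"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1, 2], test="mannwhitney")
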