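"""Group statistics against textbook-formula oracles, FDR, PCA, subset selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ambival import cohort, group


class TestCorrelations:
    def test_identical_vectors(self):
        r = group.correlate_with_symptoms([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], "caps")
        assert r.statistic == pytest.approx(1.0)
        assert r.statistic_type == "spearman_rho"

    def test_spearman_rank_invariance(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 9.0])
        a = group.correlate_with_symptoms(x, y, "caps")
        b = group.correlate_with_symptoms(np.exp(x), y, "caps")  # monotone transform
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_spearman_hand_oracle_six_points(self):
        # distinct ranks: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        x = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
        y = [1.2, 0.9, 2.5, 2.0, 3.3, 3.1]
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        rho = 1 - 6 * np.sum((rx - ry) ** 2) / (6 * 35)
        got = group.correlate_with_symptoms(x, y, "caps")
        assert got.statistic == pytest.approx(rho, abs=1e-12)

    def test_pearson_hand_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 3.5, 6.0, 8.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        got = group.correlate_with_symptoms(x, y, "pcl5")
        assert got.statistic == pytest.approx(num / den, abs=1e-12)
        assert got.statistic_type == "pearson_r"

    def test_nan_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 3.0, 5.0, 4.0, 6.0]
        r = group.correlate_with_symptoms(x, y, "pc")
        assert r.n == 5

    def test_validation(self):
        with pytest.raises(ValueError, match="paired"):
            group.correlate_with_symptoms([1, 2], [1, 2, 3], "caps")
        with pytest.raises(ValueError, match="kind"):
            group.correlate_with_symptoms([1, 2, 3, 4], [1, 2, 3, 4], "bogus")


class TestOneSampleAndWelch:
    def test_one_sample_t_hand_oracle(self):
        x = np.array([0.3, 0.1, 0.4, 0.2, 0.6, 0.5, 0.15])
        t_hand = x.mean() / (x.std(ddof=1) / math.sqrt(len(x)))
        res = group.value_saliency_group_tests(
            np.concatenate([x, x]), np.concatenate([x, x]),
            ["control"] * len(x) + ["ptsd"] * len(x),
        )
        by = {r.analysis: r for r in res}
        assert by["value_control_vs_0"].statistic == pytest.approx(t_hand, abs=1e-8)
        assert by["value_control_vs_0"].df == len(x) - 1

    def test_welch_hand_oracle(self):
        a = np.array([0.1, 0.5, 0.2, 0.9, 0.4, 0.3])
        b = np.array([-0.2, 0.1, -0.5, 0.0])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        res = group.value_saliency_group_tests(
            np.concatenate([a, b]), np.concatenate([a, b]),
            ["control"] * len(a) + ["ptsd"] * len(b),
        )
        welch = {r.analysis: r for r in res}["saliency_control_vs_ptsd"]
        assert welch.statistic == pytest.approx(t_hand, abs=1e-8)
        assert welch.df == pytest.approx(df_hand, abs=1e-8)

    def test_welch_df_equals_pooled_for_equal_variance_equal_n(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 10.0  # identical spread
        df = group._welch_df(a, b)
        assert df == pytest.approx(len(a) + len(b) - 2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            group.value_saliency_group_tests(
                [1, 2, 3, 4], [1, 2, 3, 4], ["control", "control", "control", "ptsd"]
            )


def _bh_bruteforce(p):
    """Literal Benjamini-Hochberg step-up, O(n^2) and index-free."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj


class TestFdr:
    def test_hand_applied_example(self):
        adj, rej = group.fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_single_p_unchanged(self):
        adj, _ = group.fdr_correct([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_all_ones(self):
        adj, rej = group.fdr_correct([1.0, 1.0, 1.0])
        assert np.allclose(adj, 1.0) and not rej.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            group.fdr_correct([0.5, 1.2])

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_stepup(self, data):
        n = data.draw(st.integers(1, 20))
        p = data.draw(
            st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=n, max_size=n)
        )
        adj, _ = group.fdr_correct(p)
        assert np.allclose(adj, _bh_bruteforce(p), atol=1e-12)


class TestCovariateAdjusted:
    def _frame(self, n, seed, caps_effect):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "caps_total": rng.uniform(0, 100, n),
                "age": rng.uniform(23, 70, n),
                "income_band": rng.integers(1, 4, n),
                "education_band": rng.integers(1, 4, n),
                "kbit": rng.normal(105, 12, n),
                "bic": rng.normal(200, 20, n),
            }
        )
        df["outcome"] = caps_effect * df["caps_total"] + rng.normal(0, 1.0, n)
        return df

    def test_pure_caps_effect_detected(self):
        df = self._frame(60, 0, caps_effect=0.5)
        res = group.covariate_adjusted_effect(df, "outcome")
        assert res.p_raw < 1e-10
        assert res.statistic_type == "F" and res.df[0] == 1

    def test_three_level_band_adds_two_columns(self):
        import statsmodels.formula.api as smf

        df = self._frame(60, 1, caps_effect=0.0)
        fit = smf.ols(
            "outcome ~ caps_total + age + C(income_band) + C(education_band) + kbit + bic",
            data=df,
        ).fit()
        income_cols = [c for c in fit.params.index if "income_band" in c]
        assert len(income_cols) == 2  # 3 levels -> 2 dummies

    def test_null_f_near_one_on_average(self):
        fs = [
            group.covariate_adjusted_effect(self._frame(200, s, 0.0), "outcome").statistic
            for s in range(60)
        ]
        assert np.mean(fs) == pytest.approx(1.0, abs=0.35)

    def test_too_few_cases(self):
        with pytest.raises(ValueError, match="complete cases"):
            group.covariate_adjusted_effect(self._frame(8, 0, 0.0), "outcome")


class TestSubsetSelection:
    def test_two_predictor_hand_enumeration(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        y = 2.0 * X["a"].to_numpy() + rng.normal(0, 0.5, 30)
        res = group.exhaustive_subset_selection(y, X)
        assert len(res.table) == 3  # {a}, {b}, {a,b}
        # oracle: normal-equations OLS + the documented BIC, by hand
        for _, row in res.table.iterrows():
            cols = list(row["subset"])
            Xs = np.column_stack([np.ones(30), X[cols].to_numpy()])
            beta = np.linalg.solve(Xs.T @ Xs, Xs.T @ y)
            rss = np.sum((y - Xs @ beta) ** 2)
            bic = 30 * math.log(rss / 30) + (len(cols) + 1) * math.log(30)
            assert row["bic"] == pytest.approx(bic, abs=1e-10)
        assert res.best_set == ("a",)

    def test_best_never_beaten_by_table(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        y = X["c"].to_numpy() - 0.5 * X["e"].to_numpy() + rng.normal(0, 0.3, 40)
        res = group.exhaustive_subset_selection(y, X)
        assert res.best_bic == res.table["bic"].min()
        assert len(res.table) == 2**5 - 1

    def test_matches_independent_enumeration_p4(self):
        """Full ranked table equals an independent statsmodels enumeration."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(35, 4)), columns=list("wxyz"))
        y = 1.5 * X["x"].to_numpy() + rng.normal(0, 0.4, 35)
        res = group.exhaustive_subset_selection(y, X)
        oracle = []
        n = len(y)
        for k in range(1, 5):
            for combo in itertools.combinations(X.columns, k):
                fit = sm.OLS(y, sm.add_constant(X[list(combo)])).fit()
                rss = float(fit.ssr)
                oracle.append((combo, n * math.log(rss / n) + (k + 1) * math.log(n)))
        oracle.sort(key=lambda t: t[1])
        got = list(zip(res.table["subset"], res.table["bic"]))
        for (cs, bs), (cg, bg) in zip(oracle, got):
            assert tuple(cs) == tuple(cg)
            assert bs == pytest.approx(bg, abs=1e-8)

    def test_duplicated_predictor_refused_with_name(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6, 7], "b": [2.0, 4, 6, 8, 10, 12, 14]})
        with pytest.raises(ValueError, match="b"):
            group.exhaustive_subset_selection(np.arange(7.0), X)

    def test_p_limit(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(40, 16)))
        X.columns = [f"c{i}" for i in range(16)]
        with pytest.raises(ValueError, match="15"):
            group.exhaustive_subset_selection(np.zeros(40), X)


@pytest.fixture(scope="module")
def measures():
    clin = cohort.clinical_frame(cohort.sample_population(55, seed=9))
    return clin[["caps_total", "bdi", "stai_trait", "des", "ces", "ctq"]], clin


class TestClinicalPca:
    def test_variance_sums_to_100(self, measures):
        res = group.pca_clinical(measures[0])
        assert res.variance_explained.sum() == pytest.approx(100.0)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_loadings_orthonormal(self, measures):
        L = group.pca_clinical(measures[0]).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(6), atol=1e-10)

    def test_pc1_tracks_severity(self, measures):
        df, clin = measures
        res = group.pca_clinical(df)
        r = np.corrcoef(res.scores["PC1"], clin["caps_total"])[0, 1]
        assert abs(r) > 0.9
        # sign convention: dominant loading positive -> PC1 increases with severity
        assert r > 0

    def test_incomplete_cases_dropped(self, measures):
        df = measures[0].copy().reset_index(drop=True)
        df.loc[0, "bdi"] = np.nan
        res = group.pca_clinical(df)
        assert res.n == len(df) - 1

    def test_too_few_cases(self, measures):
        with pytest.raises(ValueError, match="complete cases"):
            group.pca_clinical(measures[0].iloc[:4])
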