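from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

import fest
from fest.stats import all_subset_r2


def mixed_anova_oracle(df, dv="y", subject="s", within="c", between="g"):
    """From-scratch sums-of-squares decomposition for a k-group between
    x 2-level within design (equal within levels per subject)."""
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    groups = wide.index.get_level_values(between)
    y = wide.to_numpy()
    n_subj, n_lev = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    lev_means = y.mean(axis=0)
    g_labels = sorted(set(groups))
    k = len(g_labels)
    ss_between = n_lev * sum(
        (groups == g).sum() * (subj_means[groups == g].mean() - grand) ** 2 for g in g_labels
    )
    ss_subj_within = n_lev * sum(
        ((subj_means[groups == g] - subj_means[groups == g].mean()) ** 2).sum()
        for g in g_labels
    )
    ss_within = n_subj * ((lev_means - grand) ** 2).sum()
    cell = {
        (g, j): y[groups == g, j].mean() for g in g_labels for j in range(n_lev)
    }
    gm = {g: subj_means[groups == g].mean() for g in g_labels}
    ss_inter = sum(
        (groups == g).sum() * (cell[(g, j)] - gm[g] - lev_means[j] + grand) ** 2
        for g in g_labels
        for j in range(n_lev)
    )
    ss_total = ((y - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between - ss_subj_within - ss_within - ss_inter
    res = {}
    res["between"] = dict(
        F=(ss_between / (k - 1)) / (ss_subj_within / (n_subj - k)),
        np2=ss_between / (ss_between + ss_subj_within),
    )
    df_err = (n_subj - k) * (n_lev - 1)
    res["within"] = dict(
        F=(ss_within / (n_lev - 1)) / (ss_err_within / df_err),
        np2=ss_within / (ss_within + ss_err_within),
    )
    res["interaction"] = dict(
        F=(ss_inter / (k - 1) / (n_lev - 1)) / (ss_err_within / df_err),
        np2=ss_inter / (ss_inter + ss_err_within),
    )
    return res


def long_table(rng, k_groups=3, n_per_group=5, effect=1.0):
    rows = []
    for g in range(k_groups):
        for s in range(n_per_group):
            base = rng.normal(g * 0.5, 1.0)
            for j, c in enumerate(("coherent", "incoherent")):
                rows.append(
                    {
                        "listener_id": f"g{g}s{s}",
                        "group": f"G{g}",
                        "condition": c,
                        "y": base + effect * (j == 0) + rng.normal(0, 0.4),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_conditions_give_zero_within_f(self, rng):
        df = long_table(rng, effect=0.0)
        wide = df.pivot_table(index="listener_id", columns="condition", values="y")
        df = df.set_index(["listener_id", "condition"])
        # force both conditions identical per listener
        for lid in wide.index:
            df.loc[(lid, "incoherent"), "y"] = df.loc[(lid, "coherent"), "y"]
        df = df.reset_index()
        res = fest.mixed_anova(df, dv="y")
        assert res.effect("condition")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_partial_eta_sq_definition(self):
        # SS_effect = 1, SS_error = 3 -> 0.25
        assert 1.0 / (1.0 + 3.0) == 0.25

    def test_matches_sums_of_squares_oracle(self, rng):
        df = long_table(rng)
        res = fest.mixed_anova(df, dv="y")
        oracle = mixed_anova_oracle(
            df, dv="y", subject="listener_id", within="condition", between="group"
        )
        for effect, key in (
            ("group", "between"),
            ("condition", "within"),
            ("Interaction", "interaction"),
        ):
            assert res.effect(effect)["F"] == pytest.approx(oracle[key]["F"], abs=1e-8)
            assert res.effect(effect)["partial_eta_sq"] == pytest.approx(
                oracle[key]["np2"], abs=1e-8
            )

    def test_collapsed_within_reduces_to_one_way_anova(self, rng):
        df = long_table(rng, effect=0.0)
        wide = df.pivot_table(index="listener_id", columns="condition", values="y")
        dup = df.copy().set_index(["listener_id", "condition"])
        for lid in wide.index:
            dup.loc[(lid, "incoherent"), "y"] = dup.loc[(lid, "coherent"), "y"]
        dup = dup.reset_index()
        res = fest.mixed_anova(dup, dv="y")
        means = dup.groupby(["listener_id", "group"])["y"].mean().reset_index()
        f, _ = st.f_oneway(*[v["y"].to_numpy() for _, v in means.groupby("group")])
        assert res.effect("group")["F"] == pytest.approx(f, rel=1e-8)

    def test_missing_condition_rejected(self, rng):
        df = long_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            fest.mixed_anova(df, dv="y")


def make_X(rng, n, k, names=None):
    X = pd.DataFrame(
        rng.standard_normal((n, k)),
        columns=names or [f"x{i}" for i in range(k)],
    )
    return X


class TestFitRegression:
    def test_dominant_predictor_limit(self, rng):
        n = 500
        X = make_X(rng, n, 4)
        y = X["x0"] + 0.01 * rng.standard_normal(n)
        res = fest.fit_regression(y, X)
        assert res.r2 > 0.99
        assert res.coefficients.loc["x0", "r2_semipartial"] > 0.95

    def test_orthonormal_predictors_semipartial_equals_bivariate(self, rng):
        n = 40
        raw = rng.standard_normal((n, 3))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        y = 0.5 * X["a"] - 0.3 * X["b"] + 0.2 * rng.standard_normal(n)
        res = fest.fit_regression(y, X)
        for p in X.columns:
            assert res.coefficients.loc[p, "r2_semipartial"] == pytest.approx(
                res.coefficients.loc[p, "r2_bivariate"], abs=1e-10
            )

    def test_matches_normal_equation_oracle(self, rng):
        n, k = 38, 8
        X = make_X(rng, n, k)
        y = X.to_numpy() @ rng.standard_normal(k) + rng.standard_normal(n)
        res = fest.fit_regression(pd.Series(y, index=X.index), X)
        design = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(
            res.coefficients["estimate"].to_numpy(), beta[1:], atol=1e-8
        )

    def test_standardized_betas_scale_invariant(self, rng):
        n = 50
        X = make_X(rng, n, 3)
        y = pd.Series(X["x0"].to_numpy() + rng.standard_normal(n))
        res_raw = fest.fit_regression(y, X * np.array([10.0, 0.01, 3.0]))
        res_std = fest.fit_regression(y, X)
        np.testing.assert_allclose(
            res_raw.coefficients["beta"].to_numpy(),
            res_std.coefficients["beta"].to_numpy(),
            atol=1e-10,
        )

    def test_rank_deficient_rejected(self, rng):
        X = make_X(rng, 30, 2)
        X["dup"] = X["x0"]
        with pytest.raises(ValueError, match="rank"):
            fest.fit_regression(rng.standard_normal(30), X)

    def test_listwise_deletion_warns(self, rng):
        X = make_X(rng, 30, 2)
        X.iloc[0, 0] = np.nan
        with pytest.warns(UserWarning, match="listwise"):
            fest.fit_regression(rng.standard_normal(30), X)


def exact_corr_data(n=24):
    """Two predictors and an outcome with exact sample correlations
    r_y1 = r_y2 = 0.5 and r_12 = 0.5, built from an orthonormal basis."""
    rng = np.random.default_rng(7)
    raw = rng.standard_normal((n, 3))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    e1, e2, e3 = q[:, 0], q[:, 1], q[:, 2]
    x1 = e1
    x2 = 0.5 * e1 + np.sqrt(0.75) * e2
    a, b = 0.5, (0.5 - 0.25) / np.sqrt(0.75)
    y = a * e1 + b * e2 + np.sqrt(1 - a**2 - b**2) * e3
    X = pd.DataFrame({"x1": x1, "x2": x2})
    return pd.Series(y), X


class TestCommonality:
    def test_orthogonal_predictors_unique_only(self, rng):
        n = 60
        raw = rng.standard_normal((n, 2))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        X = pd.DataFrame(q, columns=["x1", "x2"])
        y = 0.6 * X["x1"] + 0.3 * X["x2"]
        com = fest.commonality_partition(y, X)
        r2_1 = np.corrcoef(y, X["x1"])[0, 1] ** 2
        r2_2 = np.corrcoef(y, X["x2"])[0, 1] ** 2
        assert com.unique("x1") == pytest.approx(r2_1, abs=1e-10)
        assert com.unique("x2") == pytest.approx(r2_2, abs=1e-10)
        assert com.components[frozenset(["x1", "x2"])] == pytest.approx(0.0, abs=1e-10)

    def test_two_predictor_closed_form(self):
        # r_y1 = r_y2 = 0.5, r_12 = 0.5:
        # R^2 = 1/3, unique = 1/12 each, shared = 1/6
        y, X = exact_corr_data()
        com = fest.commonality_partition(y, X)
        assert com.r2_full == pytest.approx(1 / 3, abs=1e-10)
        assert com.unique("x1") == pytest.approx(1 / 12, abs=1e-10)
        assert com.unique("x2") == pytest.approx(1 / 12, abs=1e-10)
        assert com.components[frozenset(["x1", "x2"])] == pytest.approx(1 / 6, abs=1e-10)

    def test_components_sum_to_r2_and_subset_identity(self, rng):
        n, k = 40, 5
        X = make_X(rng, n, k)
        y = X.to_numpy() @ rng.uniform(0.2, 1.0, k) + rng.standard_normal(n)
        y = pd.Series(y)
        com = fest.commonality_partition(y, X)
        assert sum(com.components.values()) == pytest.approx(com.r2_full, abs=1e-10)
        r2 = all_subset_r2(y, X)
        # for every subset A, components touching A sum to R^2(A)
        names = list(X.columns)
        for r in range(1, k + 1):
            for combo in combinations(names, r):
                A = frozenset(combo)
                total = sum(c for S, c in com.components.items() if S & A)
                assert total == pytest.approx(r2[A], abs=1e-10)

    def test_unique_equals_fit_regression_semipartial(self, rng):
        X = make_X(rng, 35, 4)
        y = pd.Series(X["x0"] + 0.5 * X["x1"] + rng.standard_normal(35))
        com = fest.commonality_partition(y, X)
        reg = fest.fit_regression(y, X)
        for p in X.columns:
            assert com.unique(p) == pytest.approx(
                reg.coefficients.loc[p, "r2_semipartial"], abs=1e-12
            )

    def test_suppression_gives_negative_shared_component(self, rng):
        # classic suppressor: x2 unrelated to y but correlated with x1
        n = 2000
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal(n)
        x2 = 0.6 * x1 + 0.8 * rng.standard_normal(n)
        y = x1 + 0.5 * rng.standard_normal(n) - 0.0 * x2
        # make x2 orthogonal to y but kept correlated with x1
        y = y - x2 * (np.cov(y, x2)[0, 1] / np.var(x2))
        X = pd.DataFrame({"x1": x1, "x2": x2})
        com = fest.commonality_partition(pd.Series(y), X)
        assert com.components[frozenset(["x1", "x2"])] < 0
        assert sum(com.components.values()) == pytest.approx(com.r2_full, abs=1e-10)

    def test_k_limit(self, rng):
        X = make_X(rng, 20, 13)
        with pytest.raises(ValueError, match="12"):
            fest.commonality_partition(rng.standard_normal(20), X)


class TestUniquePct:
    def test_ratio(self):
        assert fest.unique_pct_of_effect(0.150, 0.603) == pytest.approx(24.876, abs=1e-3)
        assert fest.unique_pct_of_effect(0.0, 0.5) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fest.unique_pct_of_effect(0.2, 0.0)
        with pytest.raises(ValueError):
            fest.unique_pct_of_effect(0.7, 0.6)


class TestPairwiseT:
    def test_threshold_is_alpha_over_m(self, rng):
        groups = {g: rng.normal(size=10) for g in "ABC"}
        out = fest.pairwise_t_bonferroni(groups)
        assert np.allclose(out["alpha_adjusted"], 0.05 / 3)
        out6 = fest.pairwise_t_bonferroni(groups, m=6)
        assert np.allclose(out6["alpha_adjusted"], 0.05 / 6)

    def test_identical_groups_never_reject(self, rng):
        x = rng.normal(size=12)
        out = fest.pairwise_t_bonferroni({"A": x, "B": x.copy(), "C": x.copy()})
        assert not out["significant"].any()

    def test_pooled_matches_scipy_and_welch_flag(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        pooled = fest.pairwise_t_bonferroni({"A": a, "B": b})
        t, p = st.ttest_ind(a, b, equal_var=True)
        assert pooled.loc[0, "t"] == pytest.approx(t)
        assert pooled.loc[0, "df"] == 22
        welch = fest.pairwise_t_bonferroni({"A": a, "B": b}, welch=True)
        tw, pw = st.ttest_ind(a, b, equal_var=False)
        assert welch.loc[0, "t"] == pytest.approx(tw)
        assert welch.loc[0, "p"] == pytest.approx(pw)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            fest.pairwise_t_bonferroni({"A": [1.0], "B": [1.0, 2.0]})


class TestPearsonMatrix:
    def test_perfect_correlations(self):
        x = pd.Series(np.arange(8.0))
        scores = pd.DataFrame({"oc": x})
        cov = pd.DataFrame({"same": x, "neg": -x})
        out = fest.pearson_matrix(scores, cov)
        assert out.loc["same", "oc_r"] == pytest.approx(1.0)
        assert out.loc["neg", "oc_r"] == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        out = fest.pearson_matrix(pd.DataFrame({"s": x}), pd.DataFrame({"c": y}))
        n = 8
        oracle = (n * np.sum(x * y) - x.sum() * y.sum()) / np.sqrt(
            (n * np.sum(x**2) - x.sum() ** 2) * (n * np.sum(y**2) - y.sum() ** 2)
        )
        assert out.loc["c", "s_r"] == pytest.approx(oracle, abs=1e-12)

    def test_two_tier_flags(self):
        rng = np.random.default_rng(0)
        n = 12
        x = rng.standard_normal(n)
        strong = x + 0.1 * rng.standard_normal(n)
        out = fest.pearson_matrix(
            pd.DataFrame({"s": x}), pd.DataFrame({"strong": strong})
        )
        assert out.loc["strong", "s_flag"] == "**"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fest.pearson_matrix(
                pd.DataFrame({"s": [1.0, 2.0, 3.0]}), pd.DataFrame({"c": [1.0, 1.0, 1.0]})
            )
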