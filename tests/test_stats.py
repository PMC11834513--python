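import numpy as np
import pandas as pd
import pytest

import icpmorph as im
from icpmorph.stats import (FactorSpec, auc_rank, bonferroni_adjust,
                            factorial_anova, group_ttest, logistic_auc,
                            multiple_regression, quartile_boundaries)


class TestQuartileBoundaries:
    def _values_with_quartiles(self, q1, med, q3, n=101, spread=4.0):
        # piecewise-linear inverse CDF through the requested quartiles
        u = np.linspace(0, 1, n)
        return np.interp(u, [0, 0.25, 0.5, 0.75, 1],
                         [q1 - spread, q1, med, q3, q3 + spread])

    def test_age_like_quartiles_round_up(self):
        v = self._values_with_quartiles(29.3, 49.1, 60.2)
        assert quartile_boundaries(v).boundaries == (30, 50, 61)

    def test_icp_like_quartiles_round_up(self):
        v = self._values_with_quartiles(8.6, 11.2, 14.9)
        assert quartile_boundaries(v).boundaries == (9, 12, 15)

    def test_integer_quartiles_unchanged(self):
        v = self._values_with_quartiles(2.0, 4.0, 6.0, spread=2.0)
        assert quartile_boundaries(v).boundaries == (2, 4, 6)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            quartile_boundaries(np.full(20, 7.0))

    def test_levels_partition_observations(self):
        rng = np.random.default_rng(0)
        v = rng.normal(50, 15, 500)
        spec = quartile_boundaries(v)
        levels = spec.assign(v)
        assert set(np.unique(levels)) == {1, 2, 3, 4}
        counts = np.bincount(levels)[1:]
        assert counts.min() > 0.15 * 500  # roughly comparable group sizes


def brute_force_balanced_ss(table, response, a_col, b_col):
    """Classical two-way SS decomposition for a balanced layout."""
    y = table[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_a = sum(len(g) * (g[response].mean() - grand) ** 2
               for _, g in table.groupby(a_col))
    ss_b = sum(len(g) * (g[response].mean() - grand) ** 2
               for _, g in table.groupby(b_col))
    ss_cells = sum(len(g) * (g[response].mean() - grand) ** 2
                   for _, g in table.groupby([a_col, b_col]))
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((g[response] - g[response].mean()) ** 2).sum()
                 for _, g in table.groupby([a_col, b_col]))
    return ss_a, ss_b, ss_ab, ss_err


class TestFactorialAnova:
    @staticmethod
    def _factors():
        fa = FactorSpec("age", (30, 50, 61))
        fb = FactorSpec("mean_icp", (9, 12, 15))
        return fa, fb

    @staticmethod
    def _balanced_table(n_per_cell=2, seed=5):
        rng = np.random.default_rng(seed)
        age_by_level = {1: 25, 2: 40, 3: 55, 4: 70}
        icp_by_level = {1: 8, 2: 10, 3: 14, 4: 20}
        rows = []
        for a in (1, 2, 3, 4):
            for b in (1, 2, 3, 4):
                for _ in range(n_per_cell):
                    rows.append({
                        "age": age_by_level[a], "mean_icp": icp_by_level[b],
                        "psi": 1.5 + 0.3 * a + 0.1 * b + 0.05 * a * b
                        + rng.normal(0, 0.2)})
        return pd.DataFrame(rows)

    def test_balanced_ss_match_closed_form(self):
        table = self._balanced_table()
        fa, fb = self._factors()
        res = factorial_anova(table, "psi", fa, fb)
        table = table.assign(_A=fa.assign(table["age"]),
                             _B=fb.assign(table["mean_icp"]))
        ss_a, ss_b, ss_ab, ss_err = brute_force_balanced_ss(
            table, "psi", "_A", "_B")
        assert res.terms.loc["age", "ss"] == pytest.approx(ss_a, rel=1e-8)
        assert res.terms.loc["mean_icp", "ss"] == pytest.approx(ss_b, rel=1e-8)
        assert res.terms.loc["age:mean_icp", "ss"] == \
            pytest.approx(ss_ab, rel=1e-8)
        # F ratios from the same decomposition
        ms_err = ss_err / res.terms.loc["age", "df_error"]
        assert res.terms.loc["age", "F"] == \
            pytest.approx((ss_a / 3) / ms_err, rel=1e-8)
        # partial eta2 definition
        assert res.terms.loc["age", "partial_eta2"] == \
            pytest.approx(ss_a / (ss_a + ss_err), rel=1e-8)

    def test_degrees_of_freedom(self):
        res = factorial_anova(self._balanced_table(3), "psi",
                              *self._factors())
        n = 16 * 3
        assert (res.terms["df_effect"] == [3, 3, 9]).all()
        assert (res.terms["df_error"] == n - 16).all()

    def test_null_response_small_effect_sizes(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"age": rng.uniform(18, 80, 400),
                           "mean_icp": rng.uniform(6, 20, 400),
                           "psi": rng.normal(2.5, 0.5, 400)})
        fa = quartile_boundaries(df["age"], "age")
        fb = quartile_boundaries(df["mean_icp"], "mean_icp")
        res = factorial_anova(df, "psi", fa, fb)
        assert (res.terms["partial_eta2"] < 0.08).all()
        assert (res.terms["p"] > 0.01).all()

    def test_empty_cell_raises_with_cell_name(self):
        df = self._balanced_table()
        df = df[~((df["age"] == 70) & (df["mean_icp"] == 20))]
        with pytest.raises(ValueError, match="age level 4"):
            factorial_anova(df, "psi", *self._factors())

    def test_posthoc_bonferroni_capped_and_family_sized(self):
        res = factorial_anova(self._balanced_table(3), "psi",
                              *self._factors())
        for family, df_ph in res.posthoc.items():
            m = df_ph["m_comparisons"].iloc[0]
            expected = 6 if ":" not in family else 120
            assert m == expected
            np.testing.assert_allclose(
                df_ph["p_bonferroni"],
                np.minimum(1.0, m * df_ph["p_raw"]), atol=1e-12)

    def test_injected_ordering_recovered(self, summary_cohort):
        df = summary_cohort
        fa = quartile_boundaries(df["age"], "age")
        fb = quartile_boundaries(df["mean_icp"], "mean_icp")
        a_psi = factorial_anova(df, "psi", fa, fb)
        a_amp = factorial_anova(df, "amp_icp", fa, fb)
        assert a_psi.terms.loc["age", "partial_eta2"] > \
            a_psi.terms.loc["mean_icp", "partial_eta2"]
        assert a_amp.terms.loc["mean_icp", "partial_eta2"] > \
            a_amp.terms.loc["age", "partial_eta2"]
        assert a_psi.terms.loc["age", "p"] < 0.01


class TestBonferroni:
    def test_min_of_one_and_m_times_p(self):
        p = np.array([0.001, 0.02, 0.4, 0.9])
        np.testing.assert_allclose(bonferroni_adjust(p, m=6),
                                   [0.006, 0.12, 1.0, 1.0])


class TestMultipleRegression:
    def test_response_equal_to_age_recovers_unit_beta(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"age": rng.uniform(18, 80, 200),
                           "mean_icp": rng.uniform(6, 20, 200),
                           "rotterdam": rng.integers(1, 7, 200)})
        df["psi"] = (df["age"] - df["age"].mean()) / df["age"].std(ddof=1)
        res = multiple_regression(df, "psi")
        assert res.beta["age"] == pytest.approx(1.0, abs=1e-8)
        assert abs(res.beta.drop("age")).max() < 1e-8

    def test_null_response_no_significant_betas(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"age": rng.uniform(18, 80, 400),
                           "mean_icp": rng.uniform(6, 20, 400),
                           "rotterdam": rng.integers(1, 7, 400),
                           "psi": rng.normal(0, 1, 400)})
        res = multiple_regression(df, "psi")
        assert abs(res.beta[["age", "mean_icp"]]).max() < 0.15
        assert (res.p_values > 1e-4).all()

    def test_standardized_effect_recovered_over_replicates(self):
        # injected standardized age effect of 0.4; 200 replicates at n=500
        errs = []
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            z_age = rng.normal(size=500)
            z_icp = rng.normal(size=500)
            y = 0.4 * z_age + np.sqrt(1 - 0.4 ** 2) * rng.normal(size=500)
            df = pd.DataFrame({"age": 50 + 15 * z_age,
                               "mean_icp": 12 + 4 * z_icp,
                               "rotterdam": rng.integers(1, 7, 500),
                               "psi": y})
            res = multiple_regression(df, "psi")
            errs.append(res.beta["age"] - 0.4)
        assert np.max(np.abs(errs)) < 0.15
        assert abs(np.mean(errs)) < 0.01

    def test_missing_rotterdam_dropped_and_counted(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"age": rng.uniform(18, 80, 100),
                           "mean_icp": rng.uniform(6, 20, 100),
                           "rotterdam": rng.integers(1, 7, 100).astype(float),
                           "psi": rng.normal(2.5, 0.5, 100)})
        df.loc[:33, "rotterdam"] = np.nan
        res = multiple_regression(df, "psi")
        assert res.n_dropped == 34
        assert res.n == 66

    def test_rank_deficiency_names_aliased_column(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"age": rng.uniform(18, 80, 60),
                           "rotterdam": rng.integers(1, 7, 60),
                           "psi": rng.normal(size=60)})
        df["icp_copy"] = df["age"]
        with pytest.raises(ValueError, match="aliased.*icp_copy"):
            multiple_regression(df, "psi", continuous=("age", "icp_copy"))


class TestGroupTTest:
    def test_identical_groups_null(self):
        df = pd.DataFrame({"amp_icp": np.tile([5.0, 7.0, 9.0], 4),
                           "died6m": [True, True, True, False, False, False]
                           * 2})
        res = group_ttest(df, "amp_icp")
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_summary_statistic_formula(self):
        # construct groups with exact target moments, then compare the
        # full-data t-test with the closed form from summary statistics
        def with_moments(n, mean, sd, seed):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return mean + sd * x
        g_died = with_moments(30, 11.7, 5.7, 1)
        g_surv = with_moments(135, 7.6, 2.8, 2)
        df = pd.DataFrame({
            "amp_icp": np.concatenate([g_died, g_surv]),
            "died6m": [True] * 30 + [False] * 135})
        res = group_ttest(df, "amp_icp")
        sp2 = (29 * 5.7 ** 2 + 134 * 2.8 ** 2) / 163
        t_summary = (11.7 - 7.6) / np.sqrt(sp2 * (1 / 30 + 1 / 135))
        assert res.t == pytest.approx(t_summary, rel=1e-6)
        assert res.df == 163
        assert res.mean_1 == pytest.approx(11.7)
        assert res.sd_2 == pytest.approx(2.8)
        assert res.p < 0.01

    def test_power_at_one_sd_shift(self):
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(rep)
            df = pd.DataFrame({
                "amp_icp": np.concatenate([rng.normal(0, 1, 100),
                                           rng.normal(1, 1, 100)]),
                "died6m": [False] * 100 + [True] * 100})
            hits += group_ttest(df, "amp_icp").p < 0.01
        assert hits / 200 > 0.99


def brute_force_auc(scores, outcomes):
    """O(n^2) proportion of concordant case/control pairs (ties half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestLogisticAuc:
    def test_auc_matches_pair_count_oracle(self):
        rng = np.random.default_rng(6)
        for n in (20, 57, 200):
            y = rng.uniform(size=n) < 0.3
            if y.all() or not y.any():
                continue
            s = rng.normal(size=n) + y
            s[: n // 4] = np.round(s[: n // 4], 1)  # induce some ties
            assert auc_rank(s, y) == pytest.approx(
                brute_force_auc(s, y), abs=1e-12)

    def test_independent_predictor_auc_near_half(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.normal(size=4000),
                           "died6m": rng.uniform(size=4000) < 0.3})
        res = logistic_auc(df, ["x"])
        assert res.auc == pytest.approx(0.5, abs=0.03)
        assert res.p > 0.01

    def test_perfect_predictor_flags_separation(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "died6m": [False] * 20 + [True] * 20})
        with pytest.warns(UserWarning, match="separation"):
            res = logistic_auc(df, ["x"])
        assert res.separation
        assert res.auc == pytest.approx(1.0)

    def test_missing_outcomes_dropped_and_counted(self, summary_cohort):
        df = summary_cohort.copy()
        df["died6m"] = df["died6m"].astype(object)
        df.loc[df.index[:18], "died6m"] = np.nan
        res = logistic_auc(df, ["amp_icp"])
        assert res.n_dropped == 18
        assert res.n == len(df) - 18

    def test_backward_elimination_drops_redundant_predictor(self):
        rng = np.random.default_rng(8)
        n = 1500
        z = rng.normal(size=n)
        x1 = z + rng.normal(0, 0.3, n)          # informative
        x2 = x1 + rng.normal(0, 0.2, n)          # redundant copy of x1
        x3 = rng.normal(size=n)                  # pure noise
        p = 1 / (1 + np.exp(-(-1.0 + 1.5 * z)))
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3,
                           "died6m": rng.uniform(size=n) < p})
        res = logistic_auc(df, ["x1", "x2", "x3"], eliminate=True)
        assert "x3" not in res.retained
        assert len(res.retained) < 3
        assert res.df == len(res.retained)
        assert res.chi2 > 0

    def test_chi2_against_manual_loglik_difference(self):
        rng = np.random.default_rng(9)
        n = 300
        x = rng.normal(size=n)
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-x))
        df = pd.DataFrame({"x": x, "died6m": y})
        res = logistic_auc(df, ["x"])
        import statsmodels.api as sm
        full = sm.Logit(y.astype(float), sm.add_constant(x)).fit(disp=0)
        assert res.chi2 == pytest.approx(2 * (full.llf - full.llnull),
                                         rel=1e-6)
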