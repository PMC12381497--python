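import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
import statsmodels.api as sm

from hiberlitter.stats_report import (
    aicc_correction,
    aicc_rank,
    compare_groups,
    count_model,
    mixed_model,
    posthoc,
    simple_regression,
)
from hiberlitter.trace_io import ValidationError


class TestCompareGroups:
    def test_identical_values_h_zero(self):
        res = compare_groups({"a": [5, 5, 5], "b": [5, 5, 5]}, mode="nonparametric")
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0

    def test_kw_matches_hand_rank_formula(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = compare_groups(groups, mode="nonparametric")
        # no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        n_tot = 9
        rank_means = {"a": 2.0, "b": 5.0, "c": 8.0}
        h_hand = 12.0 / (n_tot * (n_tot + 1)) * sum(
            3 * (rank_means[g] - (n_tot + 1) / 2) ** 2 for g in groups
        )
        assert res.statistic_value == pytest.approx(h_hand)
        assert res.df == 2

    def test_parametric_matches_scipy_f(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(size=12) for k in "abcd"}
        res = compare_groups(groups, mode="parametric")
        f, p = sps.f_oneway(*groups.values())
        assert res.statistic_value == pytest.approx(f)
        assert res.p_value == pytest.approx(p)
        assert res.df == (3, 44)

    def test_auto_switches_nonparametric_on_skew(self):
        rng = np.random.default_rng(1)
        groups = {k: np.exp(rng.normal(size=30) * 2) for k in "abc"}
        res = compare_groups(groups, mode="auto")
        assert res.statistic_label == "H"

    def test_needs_two_groups(self):
        with pytest.raises(ValidationError):
            compare_groups({"a": [1, 2]})


class TestPosthoc:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        res = posthoc({"a": x, "b": x}, family="tukey")
        assert res.loc[0, "p_adjusted"] > 0.99

    def test_shifted_group_pairs_significant(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(0, 1, 12),
            "b": rng.normal(0, 1, 12),
            "c": rng.normal(10, 1, 12),
        }
        res = posthoc(groups, family="tukey").set_index(["group_a", "group_b"])
        assert res.loc[("a", "c"), "p_adjusted"] < 0.001
        assert res.loc[("b", "c"), "p_adjusted"] < 0.001
        assert res.loc[("a", "b"), "p_adjusted"] > 0.05

    def test_dunn_adjustment_monotone(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(loc, 1, 10) for k, loc in zip("abcd", [0, 0.5, 1, 3])}
        res = posthoc(groups, family="dunn", adjust="holm")
        assert (res["p_adjusted"] >= res["p_unadjusted"] - 1e-12).all()

    def test_dunn_z_matches_hand_computation(self):
        # no ties: z from pooled rank means, var N(N+1)/12
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        res = posthoc(groups, family="dunn", adjust="none")
        z_hand = (2.0 - 5.0) / np.sqrt(6 * 7 / 12.0 * (1 / 3 + 1 / 3))
        assert res.loc[0, "statistic"] == pytest.approx(z_hand)


class TestCountModel:
    def test_equal_counts_no_effect(self):
        res = count_model([5, 5, 5, 5, 5, 5], ["a"] * 3 + ["b"] * 3)
        assert res.statistic_value == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0)

    def test_rate_doubling_detected(self):
        rng = np.random.default_rng(6)
        counts = np.concatenate([rng.poisson(7, 7), rng.poisson(15, 7)])
        res = count_model(counts, ["lo"] * 7 + ["hi"] * 7)
        assert res.p_value < 0.05
        rates = res.effect_summary.set_index("group")["rate"]
        assert rates["hi"] > rates["lo"]

    def test_degenerate_design_raises(self):
        with pytest.raises(ValidationError, match="degenerate"):
            count_model([3, 4, 5], ["a", "a", "b"])


class TestMixedModel:
    def test_perfect_fit_r2m_near_one(self):
        x = np.linspace(0, 1, 60)
        df = pd.DataFrame({"y": 2 * x + 1, "x": x, "g": np.repeat(list("abc"), 20)})
        res = mixed_model(df, "y", "x", "g")
        assert res.extra["marginal_r2"] > 0.95

    def test_pure_random_intercepts_r2m_near_zero(self):
        rng = np.random.default_rng(7)
        g = np.repeat(np.arange(10), 20)
        df = pd.DataFrame(
            {
                "y": rng.normal(0, 1, 10)[g] + rng.normal(0, 0.5, 200),
                "x": rng.normal(size=200),
                "g": g,
            }
        )
        res = mixed_model(df, "y", "x", "g")
        assert res.extra["marginal_r2"] < 0.05

    def test_variance_decomposition_recovery(self):
        # fixed 0.2 / random 0.3 / residual 0.5 -> R2m = 0.20
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(30):
            g = np.repeat(np.arange(20), 10)
            x = rng.normal(size=200)
            y = np.sqrt(0.2) * x + rng.normal(0, np.sqrt(0.3), 20)[g] + rng.normal(
                0, np.sqrt(0.5), 200
            )
            df = pd.DataFrame({"y": y, "x": x, "g": g})
            vals.append(mixed_model(df, "y", "x", "g").extra["marginal_r2"])
        assert np.mean(vals) == pytest.approx(0.20, abs=0.05)


class TestAiccRank:
    def test_correction_closed_form(self):
        # n=20, k=3 -> 2*3*4/16 = 1.5
        assert aicc_correction(3, 20) == pytest.approx(1.5)

    def test_correction_vanishes_large_n(self):
        assert aicc_correction(3, 10**6) < 1e-4

    def test_ranking_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        n = 40
        x = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = 1.2 * x["a"].to_numpy() - 0.7 * x["c"].to_numpy() + rng.normal(size=n)
        ranking = aicc_rank(y, x)

        # independent oracle: statsmodels OLS llf per subset
        oracle = {}
        for r in range(5):
            for subset in itertools.combinations("abcd", r):
                exog = sm.add_constant(x.loc[:, list(subset)].to_numpy(), has_constant="add")
                fit = sm.OLS(y, exog).fit()
                k = exog.shape[1] + 1
                oracle[subset] = -2 * fit.llf + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        got = dict(zip(ranking.table["predictors"], ranking.table["aicc"]))
        for subset, aicc in oracle.items():
            assert got[subset] == pytest.approx(aicc)
        assert ranking.best_model == min(oracle, key=oracle.get)
        assert ranking.table["delta_aicc"].iloc[0] == 0.0
        assert ranking.table["weight"].sum() == pytest.approx(1.0)

    def test_true_predictor_selected_often(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(50):
            x = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
            y = x["a"].to_numpy() + rng.normal(size=100)
            if aicc_rank(y, x).best_model == ("a",):
                hits += 1
        # exact-model selection rate: spurious inclusion per extra predictor is
        # P(chi2_1 > ~2.2) ~ 0.14, so P(neither of 2 included) ~ 0.74
        assert hits >= 30


class TestSimpleRegression:
    def test_exact_line_r2_one(self):
        x = np.arange(10.0)
        res = simple_regression(x, 2 * x)
        assert res.extra["r_squared"] == pytest.approx(1.0)

    def test_four_point_closed_form(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 2.0, 4.0])
        res = simple_regression(x, y)
        # closed form: r^2 = cov^2/(var_x var_y)
        r2 = np.cov(x, y, ddof=1)[0, 1] ** 2 / (np.var(x, ddof=1) * np.var(y, ddof=1))
        assert res.extra["r_squared"] == pytest.approx(r2)

    def test_null_r2_small(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=10000), rng.normal(size=10000)
        assert simple_regression(x, y).extra["r_squared"] < 0.001
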