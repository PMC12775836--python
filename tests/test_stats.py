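"""Inferential battery: summary t, rank tests, correlations, power and
sensitivity calculators, mixed ANOVA and the trial-level mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from gammarep import (compare_trial_predictors, fit_repetition_lmm,
                      min_detectable_eta_p2, mixed_anova_gg, power_two_sample_t,
                      rank_tests, spearman_corr, summary_t)


class TestSummaryT:
    def test_two_sample_pooled_formula(self):
        out = summary_t("two_sample_pooled", 12.0, 3.0, 10, 10.0, 3.0, 10)
        x = np.full(10, 12.0); x[0] += 1e-9
        # independent oracle: scipy from raw data with matching summaries
        rng = np.random.default_rng(0)
        a = rng.normal(size=10); a = (a - a.mean()) / a.std(ddof=1) * 3.0 + 12.0
        b = rng.normal(size=10); b = (b - b.mean()) / b.std(ddof=1) * 3.0 + 10.0
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=True)
        assert np.isclose(out["t"], t_ref, atol=1e-9)
        assert np.isclose(out["p"], p_ref, atol=1e-9)
        assert out["df"] == 18

    def test_equal_means_give_zero_t(self):
        out = summary_t("two_sample_pooled", 5.0, 1.0, 8, 5.0, 2.0, 9)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_one_sample_against_zero(self):
        out = summary_t("one_sample", 2.0, 4.0, 16)
        assert np.isclose(out["t"], 2.0) and out["df"] == 15

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            summary_t("two_sample_pooled", 1.0, 0.0, 5, 2.0, 1.0, 5)
        with pytest.raises(ValueError):
            summary_t("median", 1.0, 1.0, 5)


class TestRankTests:
    def test_identical_samples(self):
        out = rank_tests([1, 2, 3, 4], [1, 2, 3, 4])
        assert out["Z"] == 0.0 and out["p"] == 1.0 and out["r"] == 0.0

    def test_complete_separation_against_enumeration_oracle(self):
        x = np.arange(1, 11)
        y = np.arange(11, 21)
        out = rank_tests(x, y)
        assert out["U"] == 0.0
        exact = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert np.isclose(exact.pvalue, 2.0 / comb(20, 10, exact=True))
        assert out["p"] < 0.001 and out["r"] < -0.8

    def test_effect_size_identity(self):
        rng = np.random.default_rng(1)
        out = rank_tests(rng.normal(size=26), rng.normal(0.5, 1, size=27))
        assert np.isclose(out["r"], out["Z"] / np.sqrt(53))

    def test_all_tied_values(self):
        out = rank_tests([3.0] * 5, [3.0] * 6)
        assert out["p"] == 1.0 and out["Z"] == 0.0


class TestSpearman:
    def test_perfectly_monotone(self):
        assert np.isclose(spearman_corr([1, 2, 3, 4, 5], [10, 20, 25, 30, 100])["R"], 1.0)

    def test_hand_table(self):
        # ranks x (1,2,3), y (2,1,3): rs = 1 - 6*(1+1+0)/24 = 0.5
        out = spearman_corr([1, 2, 3, 4], [2, 1, 3, 4])
        d2 = np.sum((sps.rankdata([1, 2, 3, 4]) - sps.rankdata([2, 1, 3, 4])) ** 2)
        assert np.isclose(out["R"], 1 - 6 * d2 / (4 * 15))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            if spearman_corr(rng.normal(size=50), rng.normal(size=50))["p"] < 0.05:
                hits += 1
        assert 0.03 <= hits / n_sim <= 0.08

    def test_p_values_uniform_under_null(self):
        rng = np.random.default_rng(3)
        ps = [spearman_corr(rng.normal(size=50), rng.normal(size=50))["p"]
              for _ in range(500)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestPower:
    def test_zero_effect_gives_alpha(self):
        assert np.isclose(power_two_sample_t(0.0, 20, 20, 0.05, "one"), 0.05, atol=1e-9)
        assert np.isclose(power_two_sample_t(0.0, 20, 20, 0.05, "two"), 0.05, atol=1e-9)

    def test_monotone_in_effect_size(self):
        grid = [power_two_sample_t(d, 26, 27) for d in np.linspace(0, 2, 21)]
        assert np.all(np.diff(grid) > 0)

    def test_against_monte_carlo_oracle(self):
        d, n1, n2 = 0.74, 26, 27
        df = n1 + n2 - 2
        se = np.sqrt(1 / n1 + 1 / n2)
        rng = np.random.default_rng(4)
        n_sim = 100_000
        diff = rng.normal(d, se, n_sim)
        s2 = rng.chisquare(df, n_sim) / df
        t = diff / (np.sqrt(s2) * se)
        mc = np.mean(t > sps.t.ppf(0.95, df))
        assert abs(power_two_sample_t(d, n1, n2, 0.05, "one") - mc) < 0.01


class TestSensitivity:
    def test_matches_grid_search_oracle(self):
        df1, df2, N = 3, 60, 40
        eta = min_detectable_eta_p2(df1, df2, N)
        fcrit = sps.f.ppf(0.95, df1, df2)
        lams = np.arange(0.001, 50, 0.001)
        powers = sps.ncf.sf(fcrit, df1, df2, lams)
        lam_grid = lams[np.argmin(np.abs(powers - 0.80))]
        eta_grid = (lam_grid / N) / (1 + lam_grid / N)
        assert abs(eta - eta_grid) < 1e-4

    def test_power_to_alpha_limit_gives_vanishing_effect(self):
        eta = min_detectable_eta_p2(1, 50, 53, alpha=0.05, power=0.051)
        assert eta < 0.001


def _toy_mixed_dataset():
    rng = np.random.default_rng(5)
    rows = []
    for i, g in enumerate(["VSS", "VSS", "control", "control"]):
        for c in (0.0, 1.2):
            rows.append({"subject_id": f"s{i}", "group": g, "condition": c,
                         "y": rng.normal(loc=(1.0 if g == "VSS" else 0.0)
                                         + (0.5 if c else 0.0))})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_two_level_within_epsilon_is_one(self):
        aov = mixed_anova_gg(_toy_mixed_dataset(), dv="y")
        eps = aov.set_index("effect").loc["condition", "gg_epsilon"]
        assert np.isclose(eps, 1.0)

    def test_eta_p2_matches_explicit_sums(self):
        df = _toy_mixed_dataset()
        aov = mixed_anova_gg(df, dv="y").set_index("effect")
        y = df.pivot_table(index="subject_id", columns="condition", values="y")
        groups = df.groupby("subject_id")["group"].first().loc[y.index]
        grand = float(y.to_numpy().mean())
        b = y.shape[1]
        subj_mean = {s: float(y.loc[s].mean()) for s in y.index}
        grp_mean = {g: float(np.mean([subj_mean[s] for s in y.index if groups[s] == g]))
                    for g in ("VSS", "control")}
        n_g = {g: sum(groups == g) for g in ("VSS", "control")}
        # between-subject stratum
        ss_group = sum(b * n_g[g] * (grp_mean[g] - grand) ** 2 for g in grp_mean)
        ss_sw = b * sum((subj_mean[s] - grp_mean[groups[s]]) ** 2 for s in y.index)
        assert np.isclose(aov.loc["group", "eta_p2"], ss_group / (ss_group + ss_sw))
        # within-subject stratum
        cond_mean = {c: float(y[c].mean()) for c in y.columns}
        ss_cond = y.shape[0] * sum((cond_mean[c] - grand) ** 2 for c in y.columns)
        cell_mean = {(g, c): float(y.loc[groups == g, c].mean())
                     for g in grp_mean for c in y.columns}
        ss_inter = sum(n_g[g] * (cell_mean[g, c] - grp_mean[g] - cond_mean[c] + grand) ** 2
                       for g in grp_mean for c in y.columns)
        resid = sum((float(y.loc[s, c]) - cell_mean[groups[s], c]
                     - subj_mean[s] + grp_mean[groups[s]]) ** 2
                    for s in y.index for c in y.columns)
        assert np.isclose(aov.loc["condition", "eta_p2"], ss_cond / (ss_cond + resid))
        assert np.isclose(aov.loc["Interaction", "eta_p2"], ss_inter / (ss_inter + resid))

    def test_compound_symmetry_gives_epsilon_near_one(self):
        # the GG epsilon estimate is consistent under sphericity: with many
        # subjects per simulated dataset its median sits near 1
        rng = np.random.default_rng(6)
        eps_vals = []
        for _ in range(100):
            rows = []
            for s in range(160):
                u = rng.normal()
                g = "VSS" if s < 80 else "control"
                for c in range(5):
                    rows.append({"subject_id": f"s{s}", "group": g,
                                 "condition": c, "y": u + rng.normal()})
            aov = mixed_anova_gg(pd.DataFrame(rows), dv="y").set_index("effect")
            eps_vals.append(aov.loc["condition", "gg_epsilon"])
        assert np.median(eps_vals) >= 0.95

    def test_incomplete_grid_drops_subject(self):
        df = _toy_mixed_dataset()
        extra = pd.DataFrame([{"subject_id": "s9", "group": "VSS",
                               "condition": 0.0, "y": 1.0}])
        with pytest.warns(UserWarning, match="incomplete"):
            aov = mixed_anova_gg(pd.concat([df, extra], ignore_index=True), dv="y")
        assert len(aov) == 3

    def test_covariate_residualization_reduces_covariate_effect(self):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(20):
            g = "VSS" if s < 10 else "control"
            age = rng.normal()
            for c in (0.0, 1.2):
                rows.append({"subject_id": f"s{s}", "group": g, "condition": c,
                             "age": age, "y": 2.0 * age + rng.normal()})
        df = pd.DataFrame(rows)
        raw = mixed_anova_gg(df, dv="y").set_index("effect")
        adj = mixed_anova_gg(df, dv="y", covariate="age").set_index("effect")
        # removing age variance shrinks the between-subject error term noise
        assert np.isfinite(adj.loc["group", "F"])


def _linear_trial_table(slope=0.003, noise=0.0, n_sub=6, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        g = "VSS" if s < n_sub // 2 else "control"
        for n in range(15, 138):
            rows.append({"subject_id": f"s{s}", "group": g, "condition": 1.2,
                         "trialN": n,
                         "st_power": 100 * (slope * n + 0.5 + noise * rng.normal())})
    return pd.DataFrame(rows)


class TestRepetitionLMM:
    def test_noiseless_linear_response_recovered_exactly(self):
        res = fit_repetition_lmm(_linear_trial_table())
        est = res.term("trialN")["estimate"]
        assert np.isclose(est, 0.003, atol=1e-8)
        assert np.isclose(res.per100["trialN"], 0.3, atol=1e-6)

    def test_single_group_rejected(self):
        tab = _linear_trial_table()
        with pytest.raises(ValueError, match="both groups"):
            fit_repetition_lmm(tab[tab["group"] == "VSS"])

    def test_identical_predictors_tie(self):
        cmp = compare_trial_predictors(_linear_trial_table(noise=0.05, seed=1))
        assert abs(cmp["delta_aic"]) < 1e-6
        assert abs(cmp["delta_loglik"]) < 1e-6

    def test_repetition_count_law_prefers_repetition_predictor(self):
        rng = np.random.default_rng(8)
        rows = []
        for s in range(8):
            g = "VSS" if s < 4 else "control"
            u = rng.normal(0, 0.1)
            for n in range(15, 138):
                c = float(rng.integers(0, 3))
                rows.append({"subject_id": f"s{s}", "group": g, "condition": c,
                             "trialN": n, "st_power": np.nan})
        tab = pd.DataFrame(rows).sort_values(["subject_id", "condition", "trialN"])
        tab["repN"] = tab.groupby(["subject_id", "condition"]).cumcount() + 1
        tab["st_power"] = 100 * (0.02 * tab["repN"]
                                 + 0.05 * rng.normal(size=len(tab)))
        cmp = compare_trial_predictors(tab.drop(columns="repN"))
        assert cmp["preferred"] == "repN"
        assert cmp["delta_aic"] > 2
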