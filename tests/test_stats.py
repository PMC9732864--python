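"""Robust regression, Welch ANOVA, logistic occurrence, moderation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ecogdist import (
    classify_effect,
    logistic_occurrence,
    moderation,
    ols_hc3,
    visual_slope_table,
    welch_anova,
)
from ecogdist.stats import moderation_joint


class TestOlsHc3:
    def test_exact_linear_data(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 3.0 + 2.0 * x + rng.normal(0, 1e-12, 20)
        res = ols_hc3(y, x, n_boot=0)
        assert res.slope == pytest.approx(2.0, abs=1e-6)
        assert res.eta_squared == pytest.approx(1.0, abs=1e-6)

    def test_hand_expanded_sandwich_n5(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.5, 4.0, 3.0, 9.0])
        # hand computation: hat matrix written out
        X = np.column_stack([np.ones(5), x])
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        e = y - X @ beta
        h = np.diag(X @ xtx_inv @ X.T)
        meat = X.T @ np.diag(e**2 / (1.0 - h) ** 2) @ X
        cov = xtx_inv @ meat @ xtx_inv
        res = ols_hc3(y, x, n_boot=0)
        assert res.hc3_se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-12)
        assert res.df_den == 3

    def test_hc3_close_to_classical_when_homoscedastic(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 5000)
        y = 1.0 + 0.5 * x + rng.normal(0, 2.0, 5000)
        res = ols_hc3(y, x, n_boot=0)
        import statsmodels.api as sm

        classical = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.hc3_se == pytest.approx(classical.bse[1], rel=0.05)

    def test_eta_squared_is_squared_pearson_r(self, rng):
        x = rng.uniform(0, 10, 50)
        y = 2 - 0.4 * x + rng.normal(0, 2, 50)
        res = ols_hc3(y, x, n_boot=0)
        assert res.eta_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-14)

    def test_orientation_swap_preserves_eta2_changes_slope(self, rng):
        x = rng.uniform(0, 10, 60)
        y = 5 + 1.5 * x + rng.normal(0, 3, 60)
        a = ols_hc3(y, x, n_boot=0)
        b = ols_hc3(x, y, n_boot=0)
        assert a.eta_squared == pytest.approx(b.eta_squared, abs=1e-12)
        assert a.slope != pytest.approx(b.slope)

    def test_bootstrap_reproducible_and_brackets_slope(self, rng):
        x = rng.uniform(0, 10, 80)
        y = 1 - 0.8 * x + rng.normal(0, 1, 80)
        a = ols_hc3(y, x, n_boot=500, seed=7)
        b = ols_hc3(y, x, n_boot=500, seed=7)
        assert (a.bootstrap_ci_low, a.bootstrap_ci_high) == (
            b.bootstrap_ci_low,
            b.bootstrap_ci_high,
        )
        assert a.bootstrap_ci_low <= a.slope <= a.bootstrap_ci_high

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_hc3([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="n >= 3"):
            ols_hc3([1.0, 2.0], [1.0, 2.0])


class TestClassifyEffect:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.05, "small"),
            (0.06, "small"),
            (0.10, "moderate"),
            (0.14, "large"),
            (0.22, "large"),
            (0.09, "moderate"),
        ],
    )
    def test_bins(self, value, expected):
        assert classify_effect(value) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_effect(1.2)
        with pytest.raises(ValueError):
            classify_effect(-0.1)


class TestLogistic:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 50, 5000)
        logit = 1.0 + np.log(0.97) * d
        occ = (rng.random(5000) < 1 / (1 + np.exp(-logit))).astype(int)
        res = logistic_occurrence(occ, d)
        assert 0.96 <= res.odds_ratio <= 0.98
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_null_coverage(self):
        # occurrence independent of distance: CI should cover OR=1 ~95%
        covered = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            d = rng.uniform(0, 50, 400)
            occ = (rng.random(400) < 0.3).astype(int)
            res = logistic_occurrence(occ, d)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert 0.90 <= covered / n_rep <= 0.99

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            logistic_occurrence(np.ones(50), np.linspace(0, 10, 50))

    def test_complete_separation_rejected(self):
        d = np.linspace(0, 50, 100)
        occ = (d > 25).astype(int)
        with pytest.raises(ValueError, match="separation|failed"):
            logistic_occurrence(occ, d)


class TestWelchAnova:
    def test_two_groups_equal_welch_t_squared(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.7, 2.5, 17)
        from scipy import stats as sps

        res = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False).statistic
        assert res.f_value == pytest.approx(t**2, abs=1e-10)

    def test_hand_computed_three_groups(self):
        groups = [
            np.array([50.0, 54.0, 58.0, 60.0, 63.0]),
            np.array([52.0, 55.0, 59.0, 61.0, 66.0, 68.0]),
            np.array([70.0, 72.0, 76.0, 79.0, 81.0]),
        ]
        # independent hand computation of Welch's statistic
        ns = np.array([len(g) for g in groups], float)
        mns = np.array([g.mean() for g in groups])
        vrs = np.array([g.var(ddof=1) for g in groups])
        w = ns / vrs
        mw = (w * mns).sum() / w.sum()
        k = 3
        num = (w * (mns - mw) ** 2).sum() / (k - 1)
        lam = ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
        f_hand = num / (1 + 2 * (k - 2) / (k**2 - 1) * lam)
        res = welch_anova(groups)
        assert res.f_value == pytest.approx(f_hand, abs=1e-10)
        assert res.df_den == pytest.approx((k**2 - 1) / (3 * lam), abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        groups = [rng.normal(m, s, n) for m, s, n in ((0, 1, 10), (1, 2, 14), (0.3, 0.6, 9))]
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat([0, 1, 2], [10, 14, 9])}
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        res = welch_anova(groups)
        assert res.f_value == pytest.approx(float(ref["F"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-10)

    def test_reduces_to_classical_under_equal_variances(self, rng):
        from scipy import stats as sps

        # identical residual vectors shifted by group means: sample
        # variances exactly equal, so Welch differs from the classical F
        # only by the Satterthwaite factor 1 + O(1/n)
        base = rng.normal(0, 1.0, 500)
        groups = [base + m for m in (0.0, 0.3, 0.6)]
        res = welch_anova(groups)
        classical = sps.f_oneway(*groups)
        assert res.f_value == pytest.approx(classical.statistic, rel=2e-3)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_anova([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])


class TestModeration:
    def test_balanced_simple_slopes_equal_per_level_ols(self, rng):
        n = 40
        x1, x2 = rng.uniform(0, 10, n), rng.uniform(0, 10, n)
        y1 = 5 - 0.5 * x1 + rng.normal(0, 1, n)
        y2 = 5 + 0.7 * x2 + rng.normal(0, 1, n)
        res = moderation(
            np.r_[y1, y2], np.r_[x1, x2], np.array(["a"] * n + ["b"] * n)
        )
        lone_a = ols_hc3(y1, x1, n_boot=0)
        lone_b = ols_hc3(y2, x2, n_boot=0)
        assert res.simple_slopes[0].slope == pytest.approx(lone_a.slope, abs=1e-10)
        assert res.simple_slopes[1].slope == pytest.approx(lone_b.slope, abs=1e-10)
        assert res.df_num == 1

    def test_detects_injected_slope_difference(self):
        rng = np.random.default_rng(11)
        n = 300
        x1, x2 = rng.uniform(0, 20, n), rng.uniform(0, 20, n)
        y1 = 20 - 0.25 * x1 + rng.normal(0, 5, n)
        y2 = 10 + 0.65 * x2 + rng.normal(0, 5, n)
        res = moderation(
            np.r_[y1, y2], np.r_[x1, x2], np.array(["fcd"] * n + ["lgg"] * n)
        )
        assert res.p_value < 0.001
        got = {s.level: s.slope for s in res.simple_slopes}
        assert got["fcd"] == pytest.approx(-0.25, abs=0.15)
        assert got["lgg"] == pytest.approx(0.65, abs=0.15)

    def test_continuous_probes_ordered_at_mean_pm_sd(self, rng):
        n = 400
        x = rng.uniform(0, 10, n)
        m = rng.uniform(5, 25, n)
        y = 1 + (0.5 + 0.1 * m) * x + rng.normal(0, 1, n)
        res = moderation(y, x, m)
        probes = [s.level for s in res.simple_slopes]
        assert probes == sorted(probes)
        assert probes[1] == pytest.approx(m.mean())
        assert probes[2] - probes[1] == pytest.approx(m.std(ddof=1))
        # slopes at the probes track the generating interaction
        assert res.simple_slopes[0].slope < res.simple_slopes[2].slope

    def test_level_with_constant_predictor_rejected(self):
        y = np.arange(12, dtype=float)
        x = np.r_[np.ones(6), np.arange(6, dtype=float)]
        m = np.array(["a"] * 6 + ["b"] * 6)
        with pytest.raises(ValueError, match="constant"):
            moderation(y, x, m)

    def test_joint_model_degrees_of_freedom(self, rng):
        # joint pathology+volume moderation: df_den = n - (2k + 4)
        n = 200
        levels = np.repeat(["a", "b", "c"], n)
        x = rng.uniform(0, 10, 3 * n)
        vol = np.repeat(rng.uniform(1, 20, 3), n) + rng.normal(0, 0.01, 3 * n)
        y = 10 + 0.3 * x + rng.normal(0, 2, 3 * n)
        res = moderation_joint(y, x, levels, vol)
        k = 3
        assert res["pathology"].df_num == k - 1
        assert res["lesion_volume"].df_num == 1
        assert res["pathology"].df_den == 3 * n - (2 * k + 2)
        assert res["pathology"].df_den == res["lesion_volume"].df_den


class TestVisualSlopes:
    def table(self, rates, dists, pats):
        return pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(len(rates))],
                "event_type": "spike",
                "channel_id": "c1",
                "max_rate": rates,
                "distance_mm": dists,
            }
        ), {f"P{i}": p for i, p in enumerate(pats)}

    def test_equal_rates_flagged(self):
        t, m = self.table([5.0, 5.0], [1.0, 9.0], ["FCD", "FCD"])
        out = visual_slope_table(t, m)
        assert bool(out.iloc[0]["flagged"])

    def test_exact_line_recovers_coefficient(self):
        rates = [1.0, 2.0, 3.0, 4.0]
        dists = [10.0 - 2.0 * r for r in rates]
        t, m = self.table(rates, dists, ["FCD"] * 4)
        out = visual_slope_table(t, m)
        assert out.iloc[0]["slope"] == pytest.approx(-2.0, abs=1e-10)
        assert out.iloc[0]["sign"] == "negative"

    def test_sign_consistency_with_generated_negative_slope(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rates = rng.uniform(1, 20, 10)
            dists = 30 - 1.0 * rates + rng.normal(0, 3, 10)
            t, m = self.table(list(rates), list(dists), ["FCD"] * 10)
            out = visual_slope_table(t, m)
            hits += out.iloc[0]["sign"] == "negative"
        assert hits >= 18
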