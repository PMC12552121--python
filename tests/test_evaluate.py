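"""Nested-model comparison: partial-F/delta-method agreement, DeLong against
an all-pairs oracle, and the liability-scale conversions."""
import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import gxeprs as gx
from gxeprs.evaluate import (
    auc_diff_test,
    delong_paired,
    liability_r2_from_auc,
    mckelvey_zavoina_r2,
    r2_diff_test,
    var_gxe_liability,
)
from gxeprs.exceptions import ConfigurationError, DegenerateInputError
from gxeprs.io import standardize
from gxeprs.prs import PRSPair
from gxeprs.target import fit_gxeprs_bt, fit_gxeprs_qt, fit_linear


def _pair(rng, n):
    return PRSPair(standardize(rng.standard_normal(n)),
                   standardize(rng.standard_normal(n)), True, 0)


class TestR2Diff:
    def test_identical_models_give_zero_delta(self):
        rng = np.random.default_rng(0)
        n = 200
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = 0.4 * pair.x_add + rng.standard_normal(n)
        fit = fit_gxeprs_qt(y, pair, e)
        res = r2_diff_test(fit, fit)
        assert res.delta == 0.0
        assert res.p_delta == pytest.approx(1.0)

    def test_partial_f_matches_statsmodels(self, qt_analysis):
        full, red = qt_analysis["full"], qt_analysis["reduced"]
        res = r2_diff_test(full, red)
        sm_full = sm.OLS(full.y, full.design).fit()
        sm_red = sm.OLS(red.y, red.design).fit()
        f_or, p_or, _ = sm_full.compare_f_test(sm_red)
        assert res.p_delta == pytest.approx(p_or, rel=1e-8)
        assert res.delta == pytest.approx(full.fit_metric - red.fit_metric)
        assert res.var_gxe_observed == res.delta

    def test_non_nested_inputs_rejected(self, qt_analysis):
        rng = np.random.default_rng(1)
        n = qt_analysis["full"].n
        other = fit_gxeprs_qt(rng.standard_normal(n), qt_analysis["pair"],
                              qt_analysis["e_t"])
        with pytest.raises(ConfigurationError):
            r2_diff_test(qt_analysis["full"], other)

    def test_asymptotic_and_partial_f_agree_in_rank(self):
        # mixed effect sizes; Spearman over replicate datasets
        rng = np.random.default_rng(2)
        p_f, p_z = [], []
        for i in range(200):
            n = 300
            pair = _pair(rng, n)
            e = standardize(rng.standard_normal(n))
            eff = [0.0, 0.05, 0.1][i % 3]
            y = 0.4 * pair.x_add + eff * (pair.x_gxe * e) + rng.standard_normal(n)
            full = fit_gxeprs_qt(y, pair, e)
            red = fit_gxeprs_qt(y, pair, e, reduced=True)
            res = r2_diff_test(full, red)
            p_f.append(res.p_delta)
            p_z.append(res.p_delta_asymptotic)
        assert stats.spearmanr(p_f, p_z).statistic > 0.99

    def test_known_delta_recovered_from_true_scores(self):
        # parameter recovery with the truth-record component scores
        deltas = []
        for s in range(20):
            cfg = gx.SimConfig(n_individuals=5000, n_snps=200, var_additive=0.3,
                               var_env_main=0.05, var_gxe=0.02, seed=500 + s)
            c = gx.simulate_cohort(cfg)
            e = c.environments["env0"].to_numpy()
            pair = PRSPair(standardize(c.truth["score_add"]),
                           standardize(c.truth["score_gxe"]), True, 0)
            full = fit_gxeprs_qt(c.phenotype_qt, pair, standardize(e))
            red = fit_gxeprs_qt(c.phenotype_qt, pair, standardize(e), reduced=True)
            deltas.append(r2_diff_test(full, red).delta)
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean() - 0.02) < 3 * se + 1e-3


class TestDelong:
    def test_hand_built_all_pairs_oracle(self):
        # 4 cases, 4 controls; oracle: exhaustive pair counting
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        s1 = np.array([3.1, 2.0, 1.5, 0.7, 2.5, 1.0, 0.5, 0.2])
        s2 = np.array([1.0, 2.2, 0.3, 0.9, 1.1, 2.0, 0.8, 0.4])
        auc1, auc2, se, p = delong_paired(y, s1, s2)

        def pair_auc(s):
            wins = 0.0
            for a in s[:4]:
                for b in s[4:]:
                    wins += 1.0 if a > b else (0.5 if a == b else 0.0)
            return wins / 16.0

        assert auc1 == pytest.approx(pair_auc(s1), abs=1e-12)
        assert auc2 == pytest.approx(pair_auc(s2), abs=1e-12)

        # oracle SE from explicitly computed placement values
        def placements(s):
            v10 = np.array([np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                                     for b in s[4:]]) for a in s[:4]])
            v01 = np.array([np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                                     for a in s[:4]]) for b in s[4:]])
            return v10, v01

        v10_1, v01_1 = placements(s1)
        v10_2, v01_2 = placements(s2)
        s10 = np.cov(np.stack([v10_1, v10_2]))
        s01 = np.cov(np.stack([v01_1, v01_2]))
        var_or = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / 4 \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / 4
        assert se == pytest.approx(np.sqrt(var_or), abs=1e-12)

    def test_identical_scores_zero_delta_p_one(self):
        rng = np.random.default_rng(3)
        y = (rng.random(100) < 0.4).astype(float)
        s = rng.standard_normal(100)
        auc1, auc2, se, p = delong_paired(y, s, s.copy())
        assert auc1 == auc2
        assert p == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        n = 500
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        lin = pair.x_add
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        full = fit_gxeprs_bt(y, pair, e)
        red = fit_gxeprs_bt(y, pair, e, reduced=True)
        a = auc_diff_test(full, red)
        # transform both fitted score vectors strictly monotonically
        import copy
        full2, red2 = copy.copy(full), copy.copy(red)
        full2.fitted = np.exp(3 * full.fitted)
        red2.fitted = np.exp(3 * red.fitted)
        b = auc_diff_test(full2, red2)
        assert a.delta == pytest.approx(b.delta, abs=1e-12)
        assert a.p_delta == pytest.approx(b.p_delta, abs=1e-12)

    def test_too_few_cases_rejected(self):
        rng = np.random.default_rng(5)
        n = 60
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = np.zeros(n)
        y[:5] = 1.0  # below the 10-case floor
        full = fit_gxeprs_bt(y, pair, e)
        red = fit_gxeprs_bt(y, pair, e, reduced=True)
        with pytest.raises(DegenerateInputError):
            auc_diff_test(full, red)

    def test_null_delta_auc_type_one_error(self):
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 300
        for _ in range(reps):
            n = 300
            pair = _pair(rng, n)
            e = standardize(rng.standard_normal(n))
            y = (rng.random(n) < 0.4).astype(float)
            full = fit_gxeprs_bt(y, pair, e)
            red = fit_gxeprs_bt(y, pair, e, reduced=True)
            if auc_diff_test(full, red).p_delta < 0.05:
                rejections += 1
        rate = rejections / reps
        # 99% binomial band around 0.05 at 300 replicates
        half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - half - 0.02 <= rate <= 0.05 + half + 0.02


class TestLiability:
    def test_equal_aucs_give_zero(self):
        assert var_gxe_liability(0.7, 0.7, K=0.2, P=0.2) == 0.0

    def test_chance_auc_maps_to_zero_r2(self):
        assert liability_r2_from_auc(0.5, K=0.2, P=0.2) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_full_auc(self):
        vals = [var_gxe_liability(a, 0.6, K=0.2, P=0.2)
                for a in (0.62, 0.66, 0.70, 0.74)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_auc_below_half_rejected(self):
        with pytest.raises(ConfigurationError):
            liability_r2_from_auc(0.45, K=0.2, P=0.2)

    def test_probit_mz_matches_ols_r2_for_gaussian_latent(self):
        # sanity: MZ R2 of a probit on a strong predictor approximates the
        # liability variance it explains in a generative check
        cfg = gx.SimConfig(n_individuals=20_000, n_snps=150, var_additive=0.3,
                           prevalence=0.3, seed=99)
        c = gx.simulate_cohort(cfg, kinds=["binary"])
        import pandas as pd
        design = pd.DataFrame({"s": standardize(c.truth["score_add"]), "const": 1.0})
        mz = mckelvey_zavoina_r2(design, c.phenotype_bt)
        assert mz == pytest.approx(0.3, abs=0.03)
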