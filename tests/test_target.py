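"""Target models: exact interpolation, nesting, AUC dual-oracle equality,
and the permutation companion test."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import gxeprs as gx
from gxeprs.exceptions import CollinearityError, ConfigurationError, DegenerateInputError
from gxeprs.io import standardize
from gxeprs.prs import PRSPair
from gxeprs.target import (
    fit_gxeprs_bt,
    fit_gxeprs_qt,
    permute_interaction,
    rank_auc,
)


def _pair(rng, n):
    return PRSPair(
        x_add=standardize(rng.standard_normal(n)),
        x_gxe=standardize(rng.standard_normal(n)),
        standardized=True, n_snps_used=0,
    )


class TestQtFit:
    def test_exact_interpolation_recovers_coefficients(self):
        rng = np.random.default_rng(0)
        n = 200
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = 0.5 * pair.x_add + 0.2 * (pair.x_gxe * e)
        fit = fit_gxeprs_qt(y, pair, e)
        assert fit.params["x_add"] == pytest.approx(0.5, abs=1e-8)
        assert fit.params["x_gxe_x_E"] == pytest.approx(0.2, abs=1e-8)
        assert fit.params["E"] == pytest.approx(0.0, abs=1e-8)
        assert fit.fit_metric == pytest.approx(1.0, abs=1e-10)

    def test_reduced_never_beats_full(self, qt_analysis):
        assert qt_analysis["reduced"].fit_metric <= qt_analysis["full"].fit_metric
        assert "x_gxe_x_E" not in qt_analysis["reduced"].params.index
        assert "x_gxe_x_E" in qt_analysis["full"].params.index

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        n = 300
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = 0.3 * pair.x_add + rng.standard_normal(n)
        a = fit_gxeprs_qt(y, pair, e)
        perm = rng.permutation(n)
        b = fit_gxeprs_qt(y[perm],
                          PRSPair(pair.x_add[perm], pair.x_gxe[perm], True, 0),
                          e[perm])
        assert np.allclose(a.params, b.params, atol=1e-10)

    def test_null_interaction_pvalues_uniform_across_replicates(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(300):
            n = 250
            pair = _pair(rng, n)
            e = standardize(rng.standard_normal(n))
            y = 0.4 * pair.x_add + rng.standard_normal(n)
            pvals.append(fit_gxeprs_qt(y, pair, e).p["x_gxe_x_E"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_design_named(self):
        rng = np.random.default_rng(3)
        n = 100
        x = standardize(rng.standard_normal(n))
        pair = PRSPair(x_add=x, x_gxe=x.copy(), standardized=True, n_snps_used=0)
        # x_gxe identical to x_add: reduced design (no product) is singular
        with pytest.raises(CollinearityError):
            fit_gxeprs_qt(rng.standard_normal(n), pair,
                          standardize(rng.standard_normal(n)), reduced=True)


class TestBtFit:
    def test_chance_auc_on_independent_labels(self):
        rng = np.random.default_rng(4)
        n = 5000
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_gxeprs_bt(y, pair, e)
        assert fit.fit_metric == pytest.approx(0.5, abs=0.02)

    def test_two_level_env_quadratic_collinear(self):
        rng = np.random.default_rng(5)
        n = 200
        pair = _pair(rng, n)
        e = rng.choice([-1.0, 1.0], size=n)
        y = (rng.random(n) < 0.5).astype(float)
        # E^2 is constant, hence collinear with the intercept
        with pytest.raises(CollinearityError, match="collinear design columns"):
            fit_gxeprs_bt(y, pair, e)

    def test_auc_rank_sum_matches_trapezoidal(self):
        # dual-oracle: midrank formula vs sklearn's trapezoidal ROC integral
        rng = np.random.default_rng(6)
        n = 3000
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        lin = 1.2 * pair.x_add - 0.5
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        fit = fit_gxeprs_bt(y, pair, e)
        assert fit.params["x_add"] > 0
        assert fit.fit_metric > 0.5
        assert fit.fit_metric == pytest.approx(
            roc_auc_score(y, fit.fitted), abs=1e-10)

    def test_rank_auc_with_ties_matches_trapezoid(self):
        rng = np.random.default_rng(7)
        y = (rng.random(500) < 0.3).astype(float)
        score = rng.integers(0, 5, size=500).astype(float)  # heavy ties
        assert rank_auc(y, score) == pytest.approx(roc_auc_score(y, score), abs=1e-10)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(8)
        pair = _pair(rng, 50)
        with pytest.raises(DegenerateInputError):
            fit_gxeprs_bt(np.zeros(50), pair, standardize(rng.standard_normal(50)))


class TestPermutation:
    def test_extreme_rank_gives_one_over_b_plus_one(self):
        rng = np.random.default_rng(9)
        n = 300
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = 2.0 * (pair.x_gxe * e) + 0.1 * rng.standard_normal(n)
        fit = fit_gxeprs_qt(y, pair, e)
        res = permute_interaction(fit, seed=1, min_perm=1000, max_perm=1000)
        assert res.n_perm == 1000
        assert res.p_perm == pytest.approx(1.0 / 1001.0)

    def test_below_floor_request_raised_to_1000(self):
        rng = np.random.default_rng(10)
        n = 200
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = rng.standard_normal(n)
        fit = fit_gxeprs_qt(y, pair, e)
        res = permute_interaction(fit, seed=2, min_perm=50, max_perm=1000)
        assert res.n_perm >= 1000

    def test_permutation_agrees_with_asymptotic_in_rank(self):
        # dual-test agreement across null replicates
        rng = np.random.default_rng(11)
        p_perm, p_asym = [], []
        for _ in range(60):
            n = 150
            pair = _pair(rng, n)
            e = standardize(rng.standard_normal(n))
            y = 0.3 * pair.x_add + rng.standard_normal(n)
            fit = fit_gxeprs_qt(y, pair, e)
            res = permute_interaction(fit, seed=int(rng.integers(2**31)),
                                      min_perm=1000, max_perm=1000)
            p_perm.append(res.p_perm)
            p_asym.append(res.p_asymptotic)
        rho = stats.spearmanr(p_perm, p_asym).statistic
        assert rho > 0.95

    def test_permutation_preserves_other_columns_jointly(self):
        # reduced-model fit identical before/after permuting the interaction
        rng = np.random.default_rng(12)
        n = 400
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = 0.4 * pair.x_add + 0.1 * (pair.x_gxe * e) + rng.standard_normal(n)
        red_before = fit_gxeprs_qt(y, pair, e, reduced=True)
        full = fit_gxeprs_qt(y, pair, e)
        X = full.design.copy()
        X["x_gxe_x_E"] = X["x_gxe_x_E"].sample(frac=1.0, random_state=0).to_numpy()
        from gxeprs.target import fit_linear
        red_cols = [c for c in X.columns if c != "x_gxe_x_E"]
        red_after = fit_linear(X[red_cols], y)
        assert np.allclose(red_before.params, red_after.params, atol=1e-12)

    def test_reduced_model_has_no_interaction_to_permute(self, qt_analysis):
        with pytest.raises(ConfigurationError):
            permute_interaction(qt_analysis["reduced"], seed=0)

    def test_binary_permutation_runs_and_is_calibrated_loosely(self):
        rng = np.random.default_rng(13)
        n = 400
        pair = _pair(rng, n)
        e = standardize(rng.standard_normal(n))
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_gxeprs_bt(y, pair, e)
        res = permute_interaction(fit, seed=3, min_perm=1000, max_perm=1000)
        # under the null, permutation p should not be extreme
        assert 0.001 < res.p_perm <= 1.0
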