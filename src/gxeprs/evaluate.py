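"""Nested-model comparison: delta-R2, delta-AUC and Var(GxE).

Quantitative traits: Var(GxE) is the difference in R-squared between the
full and reduced target models.  The estimate's sampling variance comes from
the delta method over the joint distribution of the two model-fit
correlations (Pearson-Filon/Steiger covariance of correlated correlations);
because that variance degenerates for exactly nested models under the null,
the reported ``p_delta`` is the exact one-degree-of-freedom partial-F test,
with the delta-method normal p kept alongside as ``p_delta_asymptotic``.

Binary traits: AUCs of the two models' fitted scores are compared with the
paired DeLong test (placement-value covariance).  Var(GxE) on the liability
scale is estimated two ways.  The primary estimator refits each design as a
probit companion model and differences the McKelvey-Zavoina latent-scale R2
values: under a liability-threshold trait the conditional model of the
outcome given the predictors is exactly probit (the residual liability is
Gaussian), so this route stays consistent even when individual model
components — notably the PRS-by-environment product — are non-normal.  The
AUC route (``AUC -> d = sqrt(2) * Phi^-1(AUC) -> observed-scale R2 ->
liability R2`` with the standard prevalence K / case-fraction P
transformation) is reported alongside; it assumes binormal equal-variance
scores and is biased low by roughly a tenth of the GxE component when the
interaction score is leptokurtic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigurationError, DegenerateInputError
from .target import TargetFit, rank_auc

__all__ = [
    "ComparisonResult",
    "r2_diff_test",
    "auc_diff_test",
    "var_gxe_liability",
    "var_gxe_liability_probit",
    "liability_r2_from_auc",
    "mckelvey_zavoina_r2",
    "delong_paired",
]


@dataclass
class ComparisonResult:
    metric_full: float
    metric_reduced: float
    delta: float
    se_delta: float
    p_delta: float
    var_gxe_observed: float
    var_gxe_liability: Optional[float]
    n: int
    prevalence_used: Optional[float] = None
    p_delta_asymptotic: Optional[float] = None
    var_gxe_liability_auc: Optional[float] = None
    metric_name: str = "r2"


def _check_nested(fit_full: TargetFit, fit_reduced: TargetFit) -> None:
    if fit_full.n != fit_reduced.n or len(fit_full.y) != len(fit_reduced.y):
        raise ConfigurationError("full and reduced fits use different rows")
    if not np.allclose(fit_full.y, fit_reduced.y):
        raise ConfigurationError("full and reduced fits have different outcomes")
    if not set(fit_reduced.design.columns) <= set(fit_full.design.columns):
        raise ConfigurationError("reduced design is not a subset of the full design")


def r2_diff_test(fit_full: TargetFit, fit_reduced: TargetFit) -> ComparisonResult:
    """Delta-R2 between nested OLS fits with its significance test."""
    _check_nested(fit_full, fit_reduced)
    n = fit_full.n
    y = fit_full.y
    r1 = float(np.corrcoef(y, fit_full.fitted)[0, 1])
    r2 = float(np.corrcoef(y, fit_reduced.fitted)[0, 1])
    r12 = float(np.corrcoef(fit_full.fitted, fit_reduced.fitted)[0, 1])
    delta = fit_full.fit_metric - fit_reduced.fit_metric

    # Steiger/Pearson-Filon covariance of two correlations sharing y
    var_r1 = (1.0 - r1**2) ** 2 / n
    var_r2 = (1.0 - r2**2) ** 2 / n
    cov = (
        r12 * (1.0 - r1**2 - r2**2)
        - 0.5 * r1 * r2 * (1.0 - r1**2 - r2**2 - r12**2)
    ) / n
    var_delta = 4 * r1**2 * var_r1 + 4 * r2**2 * var_r2 - 8 * r1 * r2 * cov
    se_delta = float(np.sqrt(max(var_delta, 0.0)))
    if se_delta > 0 and delta != 0:
        p_asym = float(2.0 * stats.norm.sf(abs(delta) / se_delta))
    else:
        p_asym = 1.0

    q = fit_full.k - fit_reduced.k
    if q <= 0:
        p_f = 1.0
    else:
        num = (fit_reduced.ssr - fit_full.ssr) / q
        den = fit_full.ssr / (n - fit_full.k)
        f_stat = num / den if den > 0 else np.inf
        p_f = float(stats.f.sf(max(f_stat, 0.0), q, n - fit_full.k))

    return ComparisonResult(
        metric_full=fit_full.fit_metric,
        metric_reduced=fit_reduced.fit_metric,
        delta=delta,
        se_delta=se_delta,
        p_delta=p_f,
        var_gxe_observed=delta,
        var_gxe_liability=None,
        n=n,
        p_delta_asymptotic=p_asym,
        metric_name="r2",
    )


def delong_paired(
    y: np.ndarray, score1: np.ndarray, score2: np.ndarray
) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two correlated AUCs on the same labels.

    Returns (auc1, auc2, se_delta, p_two_sided).
    """
    y = np.asarray(y, dtype=float)
    pos = y == 1
    neg = y == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise DegenerateInputError("both classes required for AUC comparison")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, s in enumerate((np.asarray(score1, float), np.asarray(score2, float))):
        x, yv = s[pos], s[neg]
        tz = stats.rankdata(np.concatenate([x, yv]))
        tx = stats.rankdata(x)
        ty = stats.rankdata(yv)
        auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[i] = (tz[:m] - tx) / n          # case placement values
        v01[i] = 1.0 - (tz[m:] - ty) / m    # control placement values
        aucs[i] = auc
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    se = float(np.sqrt(max(var, 0.0)))
    delta = aucs[0] - aucs[1]
    p = float(2.0 * stats.norm.sf(abs(delta) / se)) if se > 0 and delta != 0 else 1.0
    return float(aucs[0]), float(aucs[1]), se, p


def liability_r2_from_auc(auc: float, K: float, P: float) -> float:
    """Liability-scale variance explained implied by an AUC.

    Probit route: ``d = sqrt(2) * Phi^-1(AUC)`` (standardized case-control
    score difference), converted to observed-scale R2 via the point-biserial
    relation at case fraction P, then to the liability scale with the
    standard K, P transformation (threshold t, height z, case mean z/K).
    """
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise ConfigurationError("K and P must be in (0, 1)")
    if auc < 0.5:
        raise ConfigurationError(
            f"AUC {auc} < 0.5: fix score orientation upstream"
        )
    d = np.sqrt(2.0) * stats.norm.ppf(auc)
    pq = P * (1.0 - P)
    r2_obs = pq * d**2 / (1.0 + d**2 * pq)
    t = stats.norm.ppf(1.0 - K)
    z = stats.norm.pdf(t)
    mean_case = z / K
    C = K**2 * (1.0 - K) ** 2 / (z**2 * pq)
    theta = mean_case * (P - K) / (1.0 - K) * (mean_case * (P - K) / (1.0 - K) - t)
    return float(C * r2_obs / (1.0 + C * theta * r2_obs))


def mckelvey_zavoina_r2(design, y: np.ndarray) -> float:
    """Latent-scale R2 of a probit companion fit: var(eta)/(var(eta)+1).

    Consistent for the liability-scale variance explained when the trait is
    a thresholded Gaussian-residual liability and the sample is drawn from
    the population (no case-control ascertainment).
    """
    res = sm.Probit(np.asarray(y, dtype=float), design).fit(disp=False, maxiter=100)
    eta = np.asarray(res.predict(which="linear"), dtype=float)
    v = float(eta.var(ddof=1))
    return v / (v + 1.0)


def var_gxe_liability_probit(fit_full: TargetFit, fit_reduced: TargetFit) -> float:
    """Liability-scale Var(GxE) from the full-model probit companion alone.

    The full design's probit fit consistently estimates the latent predictor
    eta (in residual-liability SD units).  The reduced model's explained
    latent variance is the linear projection of eta onto the reduced
    columns — avoiding a reduced probit refit, which would be misspecified
    (its omitted component is not Gaussian residual liability).  The
    estimate is ``(var(eta) - var(proj eta)) / (var(eta) + 1)``, floored
    at 0.
    """
    res = sm.Probit(np.asarray(fit_full.y, dtype=float), fit_full.design).fit(
        disp=False, maxiter=100)
    eta = np.asarray(res.predict(which="linear"), dtype=float)
    var_full = float(eta.var(ddof=1))
    Xr = fit_full.design[list(fit_reduced.design.columns)].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Xr, eta, rcond=None)
    var_red = float((Xr @ beta).var(ddof=1))
    return max((var_full - var_red) / (var_full + 1.0), 0.0)


def var_gxe_liability(
    auc_full: float, auc_reduced: float, K: float, P: float
) -> float:
    """Liability-scale Var(GxE): difference of the two implied liability R2
    values, floored at 0 (in-sample AUC of a nested logistic model can
    decrease)."""
    diff = liability_r2_from_auc(auc_full, K, P) - liability_r2_from_auc(auc_reduced, K, P)
    if diff < 0:
        warnings.warn("negative liability-scale Var(GxE) floored at 0", stacklevel=2)
        return 0.0
    return float(diff)


def auc_diff_test(
    fit_full: TargetFit,
    fit_reduced: TargetFit,
    prevalence: Optional[float] = None,
    min_class: int = 10,
) -> ComparisonResult:
    """Delta-AUC between nested logistic fits with the paired DeLong test."""
    _check_nested(fit_full, fit_reduced)
    y = fit_full.y
    n_case = int(y.sum())
    n_ctrl = len(y) - n_case
    if n_case < min_class or n_ctrl < min_class:
        raise DegenerateInputError(
            f"need >= {min_class} cases and controls (have {n_case}/{n_ctrl})"
        )
    auc_f, auc_r, se, p = delong_paired(y, fit_full.fitted, fit_reduced.fitted)
    P = n_case / len(y)

    def _r2_obs(auc: float) -> float:
        d = np.sqrt(2.0) * stats.norm.ppf(auc)
        pq = P * (1.0 - P)
        return pq * d**2 / (1.0 + d**2 * pq)

    var_obs = 0.0
    var_liab = None
    var_liab_auc = None
    if auc_f >= 0.5 and auc_r >= 0.5:
        var_obs = max(_r2_obs(auc_f) - _r2_obs(auc_r), 0.0)
        if prevalence is not None:
            var_liab_auc = var_gxe_liability(auc_f, auc_r, prevalence, P)
    if prevalence is not None:
        try:
            var_liab = var_gxe_liability_probit(fit_full, fit_reduced)
        except Exception:
            warnings.warn("probit companion fit failed; falling back to the AUC route",
                          stacklevel=2)
            var_liab = var_liab_auc
    return ComparisonResult(
        metric_full=auc_f,
        metric_reduced=auc_r,
        delta=auc_f - auc_r,
        se_delta=se,
        p_delta=p,
        var_gxe_observed=var_obs,
        var_gxe_liability=var_liab,
        n=len(y),
        prevalence_used=prevalence,
        var_gxe_liability_auc=var_liab_auc,
        metric_name="auc",
    )
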