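"""GxE PRS target models.

GxEprs_QT (linear):  y  ~  a1*x_add + a2*E + a3*(x_gxe . E) + a4*x_gxe [+ covariates]
GxEprs_BT (logistic): logit P(y=1) ~ the same terms plus a5*E^2.

The quadratic environment term appears only in the binary model, where it
guards against misspecification; the linear formulation suffices for
quantitative traits.  Reduced variants drop the interaction column
(x_gxe . E); the permuted variant (QT*/BT*) refits the full model with only
that column row-permuted, which preserves the joint distribution of the
outcome with every other column and gives an empirical null for a3.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    CollinearityError,
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
)
from .prs import PRSPair

__all__ = [
    "TargetFit",
    "PermutationResult",
    "fit_gxeprs_qt",
    "fit_gxeprs_bt",
    "permute_interaction",
    "fit_linear",
    "fit_logistic",
]

INTERACTION = "x_gxe_x_E"


@dataclass
class TargetFit:
    """A fitted target model with coefficient inference and fit metric."""

    params: pd.Series
    se: pd.Series
    stat: pd.Series
    p: pd.Series
    fit_metric: float
    metric_name: str          # "r2" | "auc"
    n: int
    model_tag: str            # "QT" | "QT_reduced" | "BT" | "BT_reduced" | custom
    llf: float
    aic: float
    design: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    resid: Optional[np.ndarray] = field(default=None, repr=False)
    ssr: Optional[float] = None

    @property
    def k(self) -> int:
        return self.design.shape[1]

    @property
    def is_binary(self) -> bool:
        return self.metric_name == "auc"


def rank_auc(y: np.ndarray, score: np.ndarray) -> float:
    """AUC by the Wilcoxon/Mann-Whitney rank-sum formula with midranks."""
    y = np.asarray(y, dtype=float)
    r = stats.rankdata(score)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("AUC undefined with a single class")
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = (diag.max() * max(arr.shape) * np.finfo(float).eps) if diag.max() > 0 else 0.0
    bad = [X.columns[i] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise CollinearityError(f"collinear design columns: {bad}")


def fit_linear(design: pd.DataFrame, y: np.ndarray, model_tag: str = "OLS") -> TargetFit:
    """OLS fit of a named design (must include 'const'); R-squared metric."""
    _check_collinearity(design)
    res = sm.OLS(y, design).fit()
    return TargetFit(
        params=res.params, se=res.bse, stat=res.tvalues, p=res.pvalues,
        fit_metric=float(res.rsquared), metric_name="r2", n=int(res.nobs),
        model_tag=model_tag, llf=float(res.llf), aic=float(res.aic),
        design=design, y=np.asarray(y, dtype=float),
        fitted=np.asarray(res.fittedvalues, dtype=float),
        resid=np.asarray(res.resid, dtype=float), ssr=float(res.ssr),
    )


def fit_logistic(design: pd.DataFrame, y: np.ndarray, model_tag: str = "Logit") -> TargetFit:
    """Maximum-likelihood logistic fit; AUC of fitted probabilities vs y."""
    _check_collinearity(design)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("binary outcome has a single class")
    try:
        res = sm.Logit(y, design).fit(disp=False, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparation variants
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError(
            f"logistic fit did not converge after {res.mle_retvals.get('iterations')} iterations"
        )
    fitted = np.asarray(res.predict(), dtype=float)
    return TargetFit(
        params=res.params, se=res.bse, stat=res.tvalues, p=res.pvalues,
        fit_metric=rank_auc(y, fitted), metric_name="auc", n=int(res.nobs),
        model_tag=model_tag, llf=float(res.llf), aic=float(res.aic),
        design=design, y=y, fitted=fitted,
    )


def _assemble_design(
    prs: PRSPair,
    env: np.ndarray,
    covariates: Optional[pd.DataFrame],
    reduced: bool,
    quadratic: bool,
) -> pd.DataFrame:
    env = np.asarray(env, dtype=float)
    cols = {"x_add": prs.x_add, "E": env}
    if not reduced:
        cols[INTERACTION] = prs.x_gxe * env
    cols["x_gxe"] = prs.x_gxe
    if quadratic:
        cols["E2"] = env * env
    design = pd.DataFrame(cols)
    if covariates is not None and covariates.shape[1] > 0:
        design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
    design["const"] = 1.0
    return design


def _listwise(design: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y) & ~design.isna().any(axis=1).to_numpy()
    return design.loc[mask].reset_index(drop=True), y[mask]


def fit_gxeprs_qt(
    y: np.ndarray,
    prs: PRSPair,
    env: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    reduced: bool = False,
) -> TargetFit:
    """Fit GxEprs_QT (or its reduced variant) by least squares."""
    design = _assemble_design(prs, env, covariates, reduced, quadratic=False)
    design, yv = _listwise(design, y)
    return fit_linear(design, yv, model_tag="QT_reduced" if reduced else "QT")


def fit_gxeprs_bt(
    y: np.ndarray,
    prs: PRSPair,
    env: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    reduced: bool = False,
) -> TargetFit:
    """Fit GxEprs_BT (or its reduced variant) by logistic regression."""
    design = _assemble_design(prs, env, covariates, reduced, quadratic=True)
    design, yv = _listwise(design, y)
    return fit_logistic(design, yv, model_tag="BT_reduced" if reduced else "BT")


@dataclass
class PermutationResult:
    """Adaptive permutation test for the interaction coefficient a3."""

    p_perm: float
    n_perm: int
    observed_stat: float
    seed: int
    p_asymptotic: float

    def __post_init__(self) -> None:
        if self.n_perm < 1000:
            raise ConfigurationError("permutation count below the floor of 1000")


def _qt_interaction_stat(X: np.ndarray, y: np.ndarray, j: int) -> float:
    """t statistic of column j in a full OLS refit."""
    n, k = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    try:
        inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.nan
    beta = inv @ Xty
    rss = float(y @ y - beta @ Xty)
    sigma2 = max(rss, 0.0) / (n - k)
    se = math.sqrt(sigma2 * inv[j, j])
    return beta[j] / se if se > 0 else np.nan


def permute_interaction(
    fit: TargetFit,
    seed: int = 0,
    min_perm: int = 1000,
    max_perm: int = 1_000_000,
) -> PermutationResult:
    """Permutation null for a3: only the interaction column is row-permuted
    and the full model refitted each time.

    The permutation count is ``max(1000, ceil(100 / p_asymptotic))`` capped
    at ``max_perm`` — adaptive so that small p-values get enough resolution,
    never below the floor of 1000 (requests below the floor are raised to
    it).  The p-value uses the add-one estimator
    ``(1 + #{|stat_b| >= |stat_obs|}) / (1 + B)`` and is therefore never 0.
    """
    if INTERACTION not in fit.design.columns:
        raise ConfigurationError("fit has no interaction column; use the full model")
    j = list(fit.design.columns).index(INTERACTION)
    X = fit.design.to_numpy(dtype=float)
    col = X[:, j]
    if np.std(col) == 0.0:
        raise DegenerateInputError("interaction column has zero variance")
    p_asym = float(fit.p[INTERACTION])
    obs = float(fit.stat[INTERACTION])

    floor = max(int(min_perm), 1000)
    if p_asym > 0:
        B = max(floor, math.ceil(100.0 / p_asym))
    else:
        B = max_perm
    B = min(B, max(max_perm, floor))

    rng = np.random.default_rng(seed)
    y = fit.y
    n_exceed = 0
    binary = fit.is_binary
    if binary:
        from .gweis import _logistic_irls
    Xp = X.copy()
    for _ in range(B):
        Xp[:, j] = col[rng.permutation(len(col))]
        if binary:
            beta, cov, conv, _ = _logistic_irls(Xp, y)
            stat_b = beta[j] / math.sqrt(cov[j, j]) if conv else np.nan
        else:
            stat_b = _qt_interaction_stat(Xp, y, j)
        if np.isfinite(stat_b) and abs(stat_b) >= abs(obs):
            n_exceed += 1
    p_perm = (1.0 + n_exceed) / (1.0 + B)
    return PermutationResult(p_perm=p_perm, n_perm=B, observed_stat=obs,
                             seed=seed, p_asymptotic=p_asym)
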