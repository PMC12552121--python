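"""Discovery-stage genome-wide environment interaction scan (GWEIS).

For a quantitative trait the outcome is first adjusted for covariates
(:func:`adjust_phenotype_qt`) and each SNP is then fitted by OLS on
``{1, g, E, g*E}``; the per-SNP normal equations are assembled in bulk from a
handful of matrix products, so the scan is vectorised across SNPs.  For a
binary trait each SNP is fitted by Newton/IRLS logistic regression on
``{1, g, E, g*E, E^2, covariates}`` — the quadratic environment term guards
against misspecification of the main effect — with Wald tests for the SNP
and interaction coefficients.  Covariates stay inside the per-SNP binary
model because logistic residualisation is not exact.

Missing dosages are mean-imputed per SNP; rows missing the outcome or the
exposure are dropped listwise.  Monomorphic or otherwise non-estimable SNPs
are flagged, never silently dropped.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .exceptions import CollinearityError, ConfigurationError, DegenerateInputError

__all__ = ["GweisResult", "adjust_phenotype_qt", "run_gweis_qt", "run_gweis_bt"]


@dataclass
class GweisResult:
    """Per-SNP main-additive and interaction effect estimates."""

    table: pd.DataFrame  # snp, a1, beta_add, se_add, p_add, beta_gxe, se_gxe, p_gxe, n, estimable
    model_kind: str      # "quantitative" | "binary"
    env_name: str

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def to_sumstats(self) -> pd.DataFrame:
        cols = ["snp", "a1", "beta_add", "se_add", "p_add",
                "beta_gxe", "se_gxe", "p_gxe", "n"]
        return self.table[cols].copy()


def _design_matrix(covariates: pd.DataFrame | np.ndarray | None, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"cov{j}" for j in range(arr.shape[1])]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise CollinearityError naming the offending columns."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = [names[i] for i in range(len(names)) if diag[i] <= tol]
    if bad:
        raise CollinearityError(f"collinear design columns: {bad}")


def adjust_phenotype_qt(
    y: np.ndarray, covariates: pd.DataFrame | np.ndarray | None
) -> np.ndarray:
    """Residuals of the least-squares regression of y on intercept + covariates.

    Rows with missing y or covariates get NaN residuals (listwise at fit time).
    """
    y = np.asarray(y, dtype=float)
    C, names = _design_matrix(covariates, len(y))
    X = np.column_stack([np.ones(len(y)), C])
    names = ["const"] + names
    mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    _check_full_rank(X[mask], names)
    coef, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
    out = np.full(len(y), np.nan)
    out[mask] = y[mask] - X[mask] @ coef
    return out


def run_gweis_qt(
    genotypes: GenotypeMatrix,
    y_adj: np.ndarray,
    env: np.ndarray,
    env_name: str = "E",
) -> GweisResult:
    """Per-SNP OLS of the adjusted phenotype on {1, g, E, g*E}, vectorised.

    ``beta_add`` is the g coefficient, ``beta_gxe`` the g*E coefficient; the
    environment main effect stays in every per-SNP model (omitting it would
    bias the interaction term) but is not exported.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    env = np.asarray(env, dtype=float)
    mask = ~np.isnan(y_adj) & ~np.isnan(env)
    y = y_adj[mask]
    e = env[mask]
    n = len(y)
    if n < 5:
        raise ConfigurationError("fewer than 5 complete rows for GWEIS")
    if np.std(e) == 0.0:
        raise CollinearityError("environment is constant: interaction column collinear")
    G = genotypes.dosages[mask]
    if np.isnan(np.sum(G)):
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean[None, :], G)
    g_var = G.var(axis=0)
    estimable = g_var > 0
    m = G.shape[1]

    ones = np.ones(n)
    e2 = e * e
    G2 = G * G
    s_g = ones @ G
    s_g2 = ones @ G2
    s_eg = e @ G
    s_e2g = e @ G2      # sum g^2 * E
    s_e2_g = e2 @ G     # sum g * E^2
    s_e2g2 = e2 @ G2
    s_e = e.sum()
    s_ee = e2.sum()
    s_y = y.sum()
    s_gy = y @ G
    s_ey = float(y @ e)
    s_egy = (y * e) @ G

    XtX = np.empty((m, 4, 4))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = s_g
    XtX[:, 0, 2] = XtX[:, 2, 0] = s_e
    XtX[:, 0, 3] = XtX[:, 3, 0] = s_eg
    XtX[:, 1, 1] = s_g2
    XtX[:, 1, 2] = XtX[:, 2, 1] = s_eg
    XtX[:, 1, 3] = XtX[:, 3, 1] = s_e2g
    XtX[:, 2, 2] = s_ee
    XtX[:, 2, 3] = XtX[:, 3, 2] = s_e2_g
    XtX[:, 3, 3] = s_e2g2
    Xty = np.stack([np.full(m, s_y), s_gy, np.full(m, s_ey), s_egy], axis=1)

    beta = np.full((m, 4), np.nan)
    cov_diag = np.full((m, 4), np.nan)
    est_idx = np.flatnonzero(estimable)
    if est_idx.size:
        A = XtX[est_idx]
        b = Xty[est_idx]
        try:
            inv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            # rare singular designs beyond monomorphism: flag individually
            inv = np.full_like(A, np.nan)
            ok = np.ones(len(est_idx), dtype=bool)
            for k in range(len(est_idx)):
                try:
                    inv[k] = np.linalg.inv(A[k])
                except np.linalg.LinAlgError:
                    ok[k] = False
            estimable[est_idx[~ok]] = False
            est_idx = est_idx[ok]
            A, b, inv = A[ok], b[ok], inv[ok]
        sol = np.einsum("mij,mj->mi", inv, b)
        beta[est_idx] = sol
        yy = float(y @ y)
        rss = yy - np.einsum("mi,mi->m", sol, b)
        rss = np.clip(rss, 0.0, None)
        sigma2 = rss / (n - 4)
        cov_diag[est_idx] = sigma2[:, None] * np.einsum("mii->mi", inv)

    se = np.sqrt(np.clip(cov_diag, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 4)

    table = pd.DataFrame({
        "snp": genotypes.snp_ids,
        "a1": genotypes.a1,
        "beta_add": beta[:, 1],
        "se_add": se[:, 1],
        "p_add": pvals[:, 1],
        "beta_gxe": beta[:, 3],
        "se_gxe": se[:, 3],
        "p_gxe": pvals[:, 3],
        "n": n,
        "estimable": estimable,
    })
    table.loc[~estimable, ["beta_add", "se_add", "p_add", "beta_gxe", "se_gxe", "p_gxe"]] = np.nan
    return GweisResult(table=table, model_kind="quantitative", env_name=env_name)


def _logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Newton/IRLS logistic fit; returns (beta, cov, converged, n_iter).

    Convergence is a score-norm criterion; separation shows up as
    non-convergence or an exploding linear predictor and is flagged upstream.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    cov = np.full((k, k), np.nan)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        if np.linalg.norm(score) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(beta).max() > 1e3:
            break
    if converged:
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            converged = False
    return beta, cov, converged, it


def run_gweis_bt(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    env: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    env_name: str = "E",
) -> GweisResult:
    """Per-SNP logistic regression of y on {1, g, E, g*E, E^2, covariates}."""
    y = np.asarray(y, dtype=float)
    env = np.asarray(env, dtype=float)
    C, _ = _design_matrix(covariates, len(y))
    mask = ~np.isnan(y) & ~np.isnan(env)
    if C.shape[1]:
        mask &= ~np.isnan(C).any(axis=1)
    yv, e = y[mask], env[mask]
    n = len(yv)
    classes = np.unique(yv)
    if len(classes) < 2:
        raise DegenerateInputError("binary outcome has a single class")
    if not set(classes) <= {0.0, 1.0}:
        raise ConfigurationError("binary outcome must be coded 0/1")
    if np.std(e) == 0.0:
        raise CollinearityError("environment is constant: interaction column collinear")
    G = genotypes.dosages[mask].astype(float)
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        G = np.where(nan_mask, col_mean[None, :], G)
    g_var = G.var(axis=0)

    m = G.shape[1]
    Cm = C[mask] if C.shape[1] else np.empty((n, 0))
    fixed = np.column_stack([np.ones(n), np.zeros(n), e, np.zeros(n), e * e, Cm])
    k = fixed.shape[1]
    out = np.full((m, 4), np.nan)  # beta_add, se_add, beta_gxe, se_gxe
    estimable = g_var > 0
    converged_flags = np.zeros(m, dtype=bool)
    n_iters = np.zeros(m, dtype=int)
    for j in range(m):
        if not estimable[j]:
            continue
        X = fixed.copy()
        X[:, 1] = G[:, j]
        X[:, 3] = G[:, j] * e
        beta, cov, conv, it = _logistic_irls(X, yv)
        converged_flags[j] = conv
        n_iters[j] = it
        if conv:
            out[j, 0] = beta[1]
            out[j, 1] = np.sqrt(cov[1, 1])
            out[j, 2] = beta[3]
            out[j, 3] = np.sqrt(cov[3, 3])
    with np.errstate(invalid="ignore", divide="ignore"):
        z_add = out[:, 0] / out[:, 1]
        z_gxe = out[:, 2] / out[:, 3]
    table = pd.DataFrame({
        "snp": genotypes.snp_ids,
        "a1": genotypes.a1,
        "beta_add": out[:, 0],
        "se_add": out[:, 1],
        "p_add": 2.0 * stats.norm.sf(np.abs(z_add)),
        "beta_gxe": out[:, 2],
        "se_gxe": out[:, 3],
        "p_gxe": 2.0 * stats.norm.sf(np.abs(z_gxe)),
        "n": n,
        "estimable": estimable & converged_flags,
        "converged": converged_flags,
        "n_iter": n_iters,
    })
    return GweisResult(table=table, model_kind="binary", env_name=env_name)
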