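"""Synthetic cohort generator.

Emulates the statistical structure the GxE PRS analysis assumes: independent
biallelic SNPs at user-chosen minor allele frequencies, mutually correlated
Gaussian environmental exposures, covariates, and phenotypes built from
additive-genetic, environment-main and genotype-by-environment variance
components.  Binary traits come from a liability-threshold model: the same
continuous liability is thresholded at the theoretical (1 - prevalence)
quantile of its population distribution.

Genotypes enter the generative model centred and scaled by
``sqrt(2 * f * (1 - f))`` (the sampled population allele frequency), so a
causal effect vector with squared norm ``v`` contributes exactly ``v`` of the
phenotypic variance in expectation.  Covariate effects add variance on top of
the unit-variance genetic + environmental + residual core, so the variance
fractions in :class:`SimConfig` describe the covariate-adjusted phenotype.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Cohort, GenotypeMatrix
from .exceptions import ConfigurationError

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_environments",
    "simulate_covariates",
    "simulate_phenotype_qt",
    "simulate_phenotype_bt",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    ``var_additive``, ``var_env_main`` and ``var_gxe`` are fractions of the
    (covariate-adjusted) phenotypic variance and must sum to less than one;
    the remainder is i.i.d. Gaussian noise.  ``env_correlation`` is the
    target correlation matrix of the exposures (unit diagonal, PSD).
    ``causal_overlap`` makes the interaction-causal SNP set identical to the
    additive-causal set (the default) or disjoint from it.
    """

    n_individuals: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_envs: int = 1
    env_correlation: Optional[np.ndarray] = None
    var_additive: float = 0.0
    var_env_main: float = 0.0
    var_gxe: float = 0.0
    n_causal_add: Optional[int] = None
    n_causal_gxe: Optional[int] = None
    prevalence: float = 0.1
    covariate_spec: Sequence[tuple[str, float]] = field(default_factory=tuple)
    causal_overlap: bool = True
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0 or self.n_envs <= 0:
            raise ConfigurationError("n_individuals, n_snps and n_envs must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} must lie in (0, 0.5]")
        for name in ("var_additive", "var_env_main", "var_gxe"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name}={v} must be in [0, 1)")
        if self.var_additive + self.var_env_main + self.var_gxe >= 1.0:
            raise ConfigurationError("variance fractions must sum to < 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError(f"prevalence {self.prevalence} must be in (0, 1)")
        if self.n_causal_add is None:
            self.n_causal_add = self.n_snps
        if self.n_causal_gxe is None:
            self.n_causal_gxe = self.n_snps
        if self.n_causal_add > self.n_snps or self.n_causal_gxe > self.n_snps:
            raise ConfigurationError("causal SNP counts cannot exceed n_snps")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.env_correlation is None:
            self.env_correlation = np.eye(self.n_envs)
        self.env_correlation = np.asarray(self.env_correlation, dtype=float)
        if self.env_correlation.shape != (self.n_envs, self.n_envs):
            raise ConfigurationError("env_correlation must be n_envs x n_envs")
        if not np.allclose(np.diag(self.env_correlation), 1.0):
            raise ConfigurationError("env_correlation must have unit diagonal")
        if not np.allclose(self.env_correlation, self.env_correlation.T):
            raise ConfigurationError("env_correlation must be symmetric")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


_BASES = np.array(["A", "C", "G", "T"])


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw hard-call dosages as two Bernoulli trials at per-SNP frequencies
    sampled uniformly on ``maf_range``; a1 is the minor allele."""
    rng = config.rng(1)
    n, m = config.n_individuals, config.n_snps
    freq = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    # two Bernoulli allele draws per genotype
    dosages = rng.binomial(2, freq, size=(n, m)).astype(np.float64)
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = np.nan
    a_idx = rng.integers(0, 4, size=m)
    b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"snp{j}" for j in range(m)]),
        chrom=np.ones(m, dtype=int),
        pos=np.arange(1, m + 1) * 1000,
        a1=_BASES[a_idx],
        a2=_BASES[b_idx],
        maf=freq,
        fid=np.array([f"F{i}" for i in range(n)]),
        iid=np.array([f"I{i}" for i in range(n)]),
    )


def simulate_environments(config: SimConfig) -> pd.DataFrame:
    """Multivariate Gaussian exposures with the configured correlation.

    Returned unstandardised (marginally unit variance in the population);
    per-dataset standardisation is a pipeline step applied after the
    discovery/target split.
    """
    corr = config.env_correlation
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # allow semidefinite matrices (e.g. perfectly correlated exposures)
        w, v = np.linalg.eigh(corr)
        if w.min() < -1e-10:
            raise ConfigurationError("env_correlation is not positive semidefinite")
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = config.rng(2)
    z = rng.standard_normal((config.n_individuals, config.n_envs))
    vals = z @ chol.T
    return pd.DataFrame(vals, columns=[f"env{k}" for k in range(config.n_envs)])


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Standard-normal covariate columns named from ``covariate_spec``."""
    rng = config.rng(3)
    cols = {
        name: rng.standard_normal(config.n_individuals)
        for name, _ in config.covariate_spec
    }
    return pd.DataFrame(cols, index=range(config.n_individuals))


def _scaled_dosages(genotypes: GenotypeMatrix) -> np.ndarray:
    """Centre and scale dosages by the sampled population frequency; missing
    calls contribute 0 (i.e. the population mean)."""
    f = genotypes.maf
    sd = np.sqrt(2.0 * f * (1.0 - f))
    g = (genotypes.dosages - 2.0 * f) / sd
    if np.isnan(np.sum(g)):
        g = np.where(np.isnan(g), 0.0, g)
    return g


def _draw_effects(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Causal index sets and effect vectors scaled to the variance targets."""
    m = config.n_snps
    if config.causal_overlap:
        idx_add = rng.choice(m, size=config.n_causal_add, replace=False)
        n_shared = min(config.n_causal_gxe, config.n_causal_add)
        idx_gxe = idx_add[:n_shared]
        if config.n_causal_gxe > n_shared:
            rest = np.setdiff1d(np.arange(m), idx_add)
            idx_gxe = np.concatenate(
                [idx_gxe, rng.choice(rest, config.n_causal_gxe - n_shared, replace=False)]
            )
    else:
        if config.n_causal_add + config.n_causal_gxe > m:
            raise ConfigurationError("disjoint causal sets exceed n_snps")
        perm = rng.permutation(m)
        idx_add = perm[: config.n_causal_add]
        idx_gxe = perm[config.n_causal_add : config.n_causal_add + config.n_causal_gxe]

    def _scaled(idx: np.ndarray, target_var: float) -> np.ndarray:
        eff = np.zeros(m)
        if target_var > 0:
            raw = rng.standard_normal(len(idx))
            eff[idx] = raw * np.sqrt(target_var / np.sum(raw**2))
        return eff

    beta = _scaled(idx_add, config.var_additive)
    delta = _scaled(idx_gxe, config.var_gxe)
    return idx_add, idx_gxe, beta, delta


def _build_liability(
    genotypes: GenotypeMatrix,
    environments: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimConfig,
) -> tuple[np.ndarray, dict]:
    """Shared continuous-outcome construction for both trait kinds."""
    rng = config.rng(4)
    g = _scaled_dosages(genotypes)
    env = environments.iloc[:, 0].to_numpy()
    idx_add, idx_gxe, beta, delta = _draw_effects(config, rng)
    score_add = g @ beta
    score_gxe = g @ delta
    gamma = np.sqrt(config.var_env_main)
    var_resid = 1.0 - config.var_additive - config.var_env_main - config.var_gxe
    y = score_add + gamma * env + score_gxe * env
    cov_effects = {}
    for name, eff in config.covariate_spec:
        y = y + eff * covariates[name].to_numpy()
        cov_effects[name] = float(eff)
    y = y + rng.standard_normal(config.n_individuals) * np.sqrt(var_resid)
    truth = {
        "beta": beta,
        "delta": delta,
        "gamma": float(gamma),
        "causal_add": idx_add,
        "causal_gxe": idx_gxe,
        "score_add": score_add,
        "score_gxe": score_gxe,
        "env_name": environments.columns[0],
        "covariate_effects": cov_effects,
        "var_additive": config.var_additive,
        "var_env_main": config.var_env_main,
        "var_gxe": config.var_gxe,
        "var_residual": var_resid,
    }
    return y, truth


def simulate_phenotype_qt(
    genotypes: GenotypeMatrix,
    environments: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimConfig,
) -> tuple[np.ndarray, dict]:
    """Quantitative phenotype with the configured variance decomposition.

    The first environment column is the causal exposure in the GxE term.
    """
    return _build_liability(genotypes, environments, covariates, config)


def simulate_phenotype_bt(
    genotypes: GenotypeMatrix,
    environments: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimConfig,
) -> tuple[np.ndarray, dict]:
    """Binary phenotype: the quantitative construction thresholded at the
    theoretical (1 - prevalence) quantile of the liability distribution."""
    liab, truth = _build_liability(genotypes, environments, covariates, config)
    total_var = 1.0 + sum(e**2 for _, e in config.covariate_spec)
    threshold = stats.norm.ppf(1.0 - config.prevalence) * np.sqrt(total_var)
    y = (liab > threshold).astype(float)
    truth = dict(truth)
    truth["liability"] = liab
    truth["threshold"] = float(threshold)
    truth["prevalence"] = config.prevalence
    return y, truth


def simulate_cohort(
    config: SimConfig,
    kinds: Sequence[str] = ("quantitative",),
) -> Cohort:
    """Full cohort: genotypes, exposures, covariates and the requested
    phenotype kinds (sharing one liability per kind, independent noise)."""
    genotypes = simulate_genotypes(config)
    environments = simulate_environments(config)
    covariates = simulate_covariates(config)
    pheno_qt = pheno_bt = None
    truth: dict = {}
    if "quantitative" in kinds:
        pheno_qt, truth_qt = simulate_phenotype_qt(genotypes, environments, covariates, config)
        truth.update({f"qt_{k}" if k in ("liability",) else k: v for k, v in truth_qt.items()})
    if "binary" in kinds:
        pheno_bt, truth_bt = simulate_phenotype_bt(genotypes, environments, covariates, config)
        if not truth:
            truth.update(truth_bt)
        else:
            truth["bt"] = truth_bt
    return Cohort(
        genotypes=genotypes,
        environments=environments,
        covariates=covariates,
        phenotype_qt=pheno_qt,
        phenotype_bt=pheno_bt,
        truth=truth or None,
    )
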