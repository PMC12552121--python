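"""Forward stepwise selection over pooled per-environment model components.

The pool holds, for each environment e analysed in the single-environment
phase: x_add(e), x_gxe(e), E(e) and x_gxe(e).E(e), plus E(e)^2 for binary
outcomes — 4 columns per environment for quantitative traits, 5 for binary.
Selection starts from a covariates-only base model, greedily adds the
component with the largest AIC decrease, and stops when no candidate lowers
the AIC.  Covariates are forced into every model and are never candidates.
Ties in AIC improvement break lexicographically by component name so the
path is deterministic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import CollinearityError, ConfigurationError, ConvergenceError
from .prs import PRSPair
from .target import TargetFit, fit_linear, fit_logistic

__all__ = ["ComponentPool", "SelectionResult", "build_pool", "forward_select"]

_AIC_TOL = 1e-9


@dataclass
class ComponentPool:
    components: pd.DataFrame
    outcome_kind: str  # "quantitative" | "binary"

    @property
    def size(self) -> int:
        return self.components.shape[1]


def build_pool(
    prs_per_env: Mapping[str, PRSPair],
    envs: pd.DataFrame,
    outcome_kind: str,
) -> ComponentPool:
    """Assemble all component columns with deterministic ``env.component``
    naming; binary outcomes additionally pool E^2."""
    if outcome_kind not in ("quantitative", "binary"):
        raise ConfigurationError(f"unknown outcome_kind {outcome_kind!r}")
    missing = [e for e in envs.columns if e not in prs_per_env]
    if missing:
        raise ConfigurationError(f"no PRS pair for environments: {missing}")
    cols: dict[str, np.ndarray] = {}
    for env_name in envs.columns:
        pair = prs_per_env[env_name]
        e = envs[env_name].to_numpy(dtype=float)
        cols[f"{env_name}.x_add"] = pair.x_add
        cols[f"{env_name}.x_gxe"] = pair.x_gxe
        cols[f"{env_name}.E"] = e
        cols[f"{env_name}.x_gxe_x_E"] = pair.x_gxe * e
        if outcome_kind == "binary":
            cols[f"{env_name}.E2"] = e * e
    return ComponentPool(components=pd.DataFrame(cols), outcome_kind=outcome_kind)


@dataclass
class SelectionResult:
    selected: list[str]
    aic_trace: list[float]
    final_fit: TargetFit
    dropped: list[str]
    base_aic: float = field(default=float("nan"))


def _fit(design: pd.DataFrame, y: np.ndarray, kind: str, tag: str) -> TargetFit:
    if kind == "binary":
        return fit_logistic(design, y, model_tag=tag)
    return fit_linear(design, y, model_tag=tag)


def forward_select(
    y: np.ndarray,
    pool: ComponentPool,
    covariates: Optional[pd.DataFrame] = None,
    outcome_kind: Optional[str] = None,
) -> SelectionResult:
    """Greedy forward selection by AIC (AIC = -2 loglik + 2k, k counting all
    estimated coefficients including the intercept)."""
    kind = outcome_kind or pool.outcome_kind
    y = np.asarray(y, dtype=float)
    base_cols = {}
    if covariates is not None and covariates.shape[1] > 0:
        for c in covariates.columns:
            base_cols[c] = covariates[c].to_numpy(dtype=float)
    base = pd.DataFrame(base_cols, index=range(len(y)))
    base["const"] = 1.0

    current = base
    current_fit = _fit(current, y, kind, tag="stepwise_base")
    base_aic = current_fit.aic
    remaining = sorted(pool.components.columns)
    selected: list[str] = []
    trace: list[float] = []

    while remaining:
        best_name = None
        best_aic = current_fit.aic - _AIC_TOL
        best_fit = None
        for name in remaining:  # lexicographic order; first strict winner kept
            cand = current.copy()
            cand.insert(len(selected) + len(base_cols), name,
                        pool.components[name].to_numpy(dtype=float))
            try:
                fit = _fit(cand, y, kind, tag="stepwise")
            except (CollinearityError, ConvergenceError) as exc:
                warnings.warn(f"skipping candidate {name}: {exc}", stacklevel=2)
                continue
            if fit.aic < best_aic - _AIC_TOL:
                best_name, best_aic, best_fit = name, fit.aic, fit
        if best_name is None:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current = best_fit.design
        current_fit = best_fit
        trace.append(best_aic)

    current_fit.model_tag = "stepwise_final"
    return SelectionResult(
        selected=selected,
        aic_trace=trace,
        final_fit=current_fit,
        dropped=sorted(set(pool.components.columns) - set(selected)),
        base_aic=base_aic,
    )
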