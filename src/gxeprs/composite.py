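"""Composite environmental variables.

Two compositions of several standardized exposures into one:

* ``sum_dir`` — unweighted signed sum, each exposure entering with +1 or -1
  according to a user-supplied direction map expressing its relation to a
  healthy lifestyle (in the motivating design, healthy-diet and
  physical-activity scores enter positively and the rest negatively).
* ``PC1`` — weighted sum with weights given by the loadings of the first
  principal component of the exposures, fitted on one dataset (discovery by
  default, preventing target-set leakage into weight estimation) and applied
  unchanged to another.

Both composites are re-standardized after combination.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateInputError
from .io import standardize

__all__ = ["CompositeEnv", "make_sum_dir", "make_pc1"]


@dataclass
class CompositeEnv:
    method: str                 # "sum_dir" | "PC1"
    weights: pd.Series          # per-environment loading
    values: np.ndarray          # per-individual composite exposure
    source_envs: tuple[str, ...]
    fitted_on: str = "same"


def make_sum_dir(
    standardized_envs: pd.DataFrame, direction_map: Mapping[str, int]
) -> CompositeEnv:
    """Signed unweighted sum of standardized exposures, then standardized."""
    missing = [c for c in standardized_envs.columns if c not in direction_map]
    if missing:
        raise ConfigurationError(f"direction_map lacks environments: {missing}")
    signs = {}
    for name in standardized_envs.columns:
        s = direction_map[name]
        if s not in (1, -1, +1.0, -1.0):
            raise ConfigurationError(f"direction for {name} must be +1 or -1, got {s}")
        signs[name] = int(s)
    raw = np.zeros(len(standardized_envs))
    for name, s in signs.items():
        raw = raw + s * standardized_envs[name].to_numpy(dtype=float)
    values = standardize(raw)
    return CompositeEnv(
        method="sum_dir",
        weights=pd.Series(signs, dtype=float),
        values=values,
        source_envs=tuple(standardized_envs.columns),
    )


def make_pc1(
    fit_envs: pd.DataFrame,
    apply_envs: Optional[pd.DataFrame] = None,
    fitted_on: str = "discovery",
) -> CompositeEnv:
    """First-principal-component composite.

    Loadings are the leading eigenvector of the covariance matrix of
    ``fit_envs`` (complete rows required), sign-fixed so the
    largest-magnitude loading is positive, and applied to ``apply_envs``
    (default: the fitting data itself).
    """
    if fit_envs.shape[1] < 2:
        raise ConfigurationError("PC1 composite needs at least 2 environments")
    if fit_envs.isna().any().any():
        raise ConfigurationError("fit dataset rows must be complete for PC1")
    if apply_envs is None:
        apply_envs = fit_envs
        fitted_on = "same"
    if list(apply_envs.columns) != list(fit_envs.columns):
        apply_envs = apply_envs[list(fit_envs.columns)]
    cov = np.cov(fit_envs.to_numpy(dtype=float), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    loadings = eigvecs[:, -1]
    pivot = int(np.argmax(np.abs(loadings)))
    if loadings[pivot] < 0:
        loadings = -loadings
    raw = apply_envs.to_numpy(dtype=float) @ loadings
    try:
        values = standardize(raw)
    except DegenerateInputError:
        raise DegenerateInputError("PC1 composite has zero variance in the apply dataset")
    return CompositeEnv(
        method="PC1",
        weights=pd.Series(loadings, index=fit_envs.columns),
        values=values,
        source_envs=tuple(fit_envs.columns),
        fitted_on=fitted_on,
    )
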