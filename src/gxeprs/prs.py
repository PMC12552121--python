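"""Additive and interaction PRS construction in the target set.

``score_i = sum_j beta_hat_j * g_ij`` over the SNPs shared between the target
genotypes and the discovery summary statistics.  Allele alignment flips the
effect sign when the target a1 is the discovery a2; SNPs whose allele cannot
be reconciled, or that the scan flagged non-estimable, are excluded.  Missing
dosages contribute the SNP's mean dosage.  Scores are standardized within the
target set by default so target-model coefficients are scale-comparable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .exceptions import ConfigurationError, DegenerateInputError
from .gweis import GweisResult
from .io import standardize

__all__ = ["PRSPair", "compute_prs", "compute_prs_pair"]

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class PRSPair:
    """Per-individual additive (x_add) and interaction (x_gxe) PRS."""

    x_add: np.ndarray
    x_gxe: np.ndarray
    standardized: bool
    n_snps_used: int


def _as_table(gweis_result: GweisResult | pd.DataFrame) -> pd.DataFrame:
    if isinstance(gweis_result, GweisResult):
        return gweis_result.table
    return gweis_result


def compute_prs(
    target_genotypes: GenotypeMatrix,
    gweis_result: GweisResult | pd.DataFrame,
    which: str = "add",
    standardized: bool = True,
    p_threshold: Optional[float] = None,
    exclude_palindromic: bool = False,
) -> np.ndarray:
    """Weighted allele-count sum over estimable, allele-aligned SNPs.

    ``which`` selects the effect column ('add' or 'gxe'); ``p_threshold``
    optionally restricts to SNPs with the matching p-value below it
    (defaults to using every SNP, as no selection step is part of the
    published pipeline).
    """
    if which not in ("add", "gxe"):
        raise ConfigurationError(f"which must be 'add' or 'gxe', got {which!r}")
    table = _as_table(gweis_result)
    beta_col, p_col = f"beta_{which}", f"p_{which}"

    sum_idx = pd.Index(table["snp"])
    tgt_idx = pd.Index(target_genotypes.snp_ids)
    pos_in_table = sum_idx.get_indexer(tgt_idx)
    overlap = np.flatnonzero(pos_in_table >= 0)
    if overlap.size == 0:
        raise ConfigurationError("no overlapping SNPs between target and summary statistics")

    tab = table.iloc[pos_in_table[overlap]]
    beta = tab[beta_col].to_numpy(dtype=float)
    keep = ~np.isnan(beta)
    if "estimable" in tab.columns:
        keep &= tab["estimable"].to_numpy(dtype=bool)
    if p_threshold is not None:
        keep &= tab[p_col].to_numpy(dtype=float) <= p_threshold

    t_a1 = np.char.upper(target_genotypes.a1[overlap].astype(str))
    s_a1 = np.char.upper(tab["a1"].to_numpy(dtype=str))
    if "a2" in tab.columns:
        s_a2 = np.char.upper(tab["a2"].to_numpy(dtype=str))
    else:
        s_a2 = np.char.upper(target_genotypes.a2[overlap].astype(str))
    t_a2 = np.char.upper(target_genotypes.a2[overlap].astype(str))
    same = t_a1 == s_a1
    flipped = (t_a1 == s_a2) & (t_a2 == s_a1)
    keep &= same | flipped
    if exclude_palindromic:
        pal = np.array([(x, y) in _PALINDROMIC for x, y in zip(t_a1, t_a2)])
        keep &= ~pal

    if not keep.any():
        raise ConfigurationError("no usable SNPs after allele alignment and filtering")

    cols = overlap[keep]
    w = np.where(flipped[keep], -beta[keep], beta[keep])
    G = target_genotypes.dosages[:, cols].astype(float)
    nan_mask = np.isnan(G)
    if nan_mask.any():
        col_mean = np.nanmean(G, axis=0)
        G = np.where(nan_mask, col_mean[None, :], G)
    score = G @ w
    if standardized:
        score = standardize(score)
    return score


def compute_prs_pair(
    target_genotypes: GenotypeMatrix,
    gweis_result: GweisResult | pd.DataFrame,
    standardized: bool = True,
    **kwargs,
) -> PRSPair:
    """Both scores over the identical SNP set."""
    x_add = compute_prs(target_genotypes, gweis_result, "add",
                        standardized=standardized, **kwargs)
    x_gxe = compute_prs(target_genotypes, gweis_result, "gxe",
                        standardized=standardized, **kwargs)
    table = _as_table(gweis_result)
    n_used = int(table["estimable"].sum()) if "estimable" in table.columns else len(table)
    return PRSPair(x_add=x_add, x_gxe=x_gxe, standardized=standardized,
                   n_snps_used=n_used)
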