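"""Shared in-memory containers for cohorts and genotype matrices.

Dosages are stored as float64 with ``nan`` marking missing hard calls so that
column arithmetic (allele frequencies, mean imputation) stays vectorised; on
disk they are 2-bit PLINK codes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = ["GenotypeMatrix", "Cohort"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count dosages with SNP metadata.

    ``dosages[i, j]`` counts copies of allele ``a1[j]`` carried by individual
    ``i`` (0, 1 or 2; ``nan`` = missing).  ``maf`` stores the per-SNP minor
    allele frequency the matrix was simulated at (or computed from data when
    read from disk).
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    maf: np.ndarray
    fid: Optional[np.ndarray] = None
    iid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise FormatError("dosages must be a 2-D individuals x SNPs array")
        m = self.dosages.shape[1]
        for name in ("snp_ids", "chrom", "pos", "a1", "a2", "maf"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != m:
                raise FormatError(f"{name} has {arr.shape[0]} entries for {m} SNPs")
            setattr(self, name, arr)
        if self.fid is None:
            self.fid = np.array([f"F{i}" for i in range(self.n_individuals)])
        if self.iid is None:
            self.iid = np.array([f"I{i}" for i in range(self.n_individuals)])
        # single cheap pass: d*(d-1)*(d-2) == 0 iff d in {0,1,2}; nan propagates
        probe = self.dosages * (self.dosages - 1.0) * (self.dosages - 2.0)
        if np.any(~np.isnan(probe) & (probe != 0.0)):
            raise FormatError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Empirical a1 allele frequency per SNP, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def empirical_maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def subset_individuals(self, rows: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[rows],
            fid=self.fid[rows],
            iid=self.iid[rows],
        )


@dataclass
class Cohort:
    """A simulated or loaded cohort with all tables on one individual ordering."""

    genotypes: GenotypeMatrix
    environments: pd.DataFrame
    covariates: pd.DataFrame
    phenotype_qt: Optional[np.ndarray] = None
    phenotype_bt: Optional[np.ndarray] = None
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        n = self.genotypes.n_individuals
        for name in ("environments", "covariates"):
            tab = getattr(self, name)
            if tab is not None and len(tab) != n:
                raise FormatError(f"{name} has {len(tab)} rows for {n} individuals")
        for name in ("phenotype_qt", "phenotype_bt"):
            vec = getattr(self, name)
            if vec is not None:
                vec = np.asarray(vec, dtype=float)
                if vec.shape[0] != n:
                    raise FormatError(f"{name} length {vec.shape[0]} != {n}")
                setattr(self, name, vec)

    @property
    def n(self) -> int:
        return self.genotypes.n_individuals

    @property
    def fid(self) -> np.ndarray:
        return self.genotypes.fid

    @property
    def iid(self) -> np.ndarray:
        return self.genotypes.iid

    def subset(self, rows: np.ndarray) -> "Cohort":
        """Row-subset every component; the truth record is shared, with the
        per-individual truth scores subset alongside."""
        truth = None
        if self.truth is not None:
            truth = dict(self.truth)
            for key in ("score_add", "score_gxe", "liability"):
                if key in truth and truth[key] is not None:
                    truth[key] = np.asarray(truth[key])[rows]
        return Cohort(
            genotypes=self.genotypes.subset_individuals(rows),
            environments=self.environments.iloc[rows].reset_index(drop=True),
            covariates=self.covariates.iloc[rows].reset_index(drop=True),
            phenotype_qt=None if self.phenotype_qt is None else self.phenotype_qt[rows],
            phenotype_bt=None if self.phenotype_bt is None else self.phenotype_bt[rows],
            truth=truth,
        )
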