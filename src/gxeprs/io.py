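"""File formats and the discovery/target split.

PLINK v1 bed/bim/fam is the genotype interchange format.  The bed codec here
follows the SNP-major 2-bit encoding: per SNP, each byte packs four samples
little-endian-first, with codes ``00`` = homozygous a1 (dosage 2 counting a1
alleles), ``10`` = heterozygous (1), ``11`` = homozygous a2 (0), ``01`` =
missing.  Sample tables are whitespace-delimited text with a header and
leading FID/IID columns; missing values are coded ``NA``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import Cohort, GenotypeMatrix
from .exceptions import ConfigurationError, DegenerateInputError, FormatError

__all__ = [
    "SplitSpec",
    "read_plink",
    "write_plink",
    "split_indices",
    "split_cohort",
    "standardize",
    "read_sample_table",
    "write_sample_table",
    "write_cohort",
    "read_sumstats",
    "write_sumstats",
]

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit code -> dosage counting a1 alleles; -9 marks missing before nan cast
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

_DECODE_TABLE = np.empty((256, 4), dtype=np.float64)
for _byte in range(256):
    for _k in range(4):
        _DECODE_TABLE[_byte, _k] = _CODE_TO_DOSAGE[(_byte >> (2 * _k)) & 0b11]


def read_plink(prefix: str | Path, count_a1: bool = True) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet into a :class:`GenotypeMatrix`.

    Dosages count a1 alleles by default; ``count_a1=False`` flips to a2.
    """
    prefix = Path(prefix)
    bed_path, bim_path, fam_path = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FormatError(f"missing PLINK file: {p}")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"snp": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)
    raw = bed_path.read_bytes()
    if raw[:2] != _MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major (mode 1) bed files are supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: size {len(raw)} does not match {n} individuals x {m} SNPs"
        )
    codes = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    dosages = _DECODE_TABLE[codes].reshape(m, bytes_per_snp * 4)[:, :n].T.copy()
    if not count_a1:
        dosages = 2.0 - dosages
    f = np.nanmean(dosages, axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=bim["snp"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        a1=bim["a1"].to_numpy(),
        a2=bim["a2"].to_numpy(),
        maf=np.minimum(f, 1.0 - f),
        fid=fam["fid"].to_numpy(),
        iid=fam["iid"].to_numpy(),
    )


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam; the inverse of :func:`read_plink` for hard calls."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = genotypes.n_individuals, genotypes.n_snps
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    d = genotypes.dosages.T  # (m, n)
    codes = np.full(d.shape, 0b01, dtype=np.uint8)  # missing
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[d == dosage] = code
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())
    bim = pd.DataFrame({
        "chrom": genotypes.chrom,
        "snp": genotypes.snp_ids,
        "cm": 0,
        "pos": genotypes.pos,
        "a1": genotypes.a1,
        "a2": genotypes.a2,
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": genotypes.fid,
        "iid": genotypes.iid,
        "father": 0,
        "mother": 0,
        "sex": 0,
        "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


@dataclass
class SplitSpec:
    """8:2 discovery/target split by default."""

    discovery_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.discovery_fraction < 1.0):
            raise ConfigurationError("discovery_fraction must be in (0, 1)")


def split_indices(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint partition of ``range(n)``.

    The discovery size is ``round(fraction * n)`` with round-half-to-even;
    288,792 individuals at 0.8 therefore split 231,034 / 57,758.
    """
    if n <= 0:
        raise ConfigurationError("cannot split an empty cohort")
    n_disc = int(round(spec.discovery_fraction * n))
    if n_disc == 0 or n_disc == n:
        raise ConfigurationError(
            f"fraction {spec.discovery_fraction} leaves an empty partition at n={n}"
        )
    perm = np.random.default_rng(spec.seed).permutation(n)
    return np.sort(perm[:n_disc]), np.sort(perm[n_disc:])


def split_cohort(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    disc_idx, targ_idx = split_indices(cohort.n, spec)
    return cohort.subset(disc_idx), cohort.subset(targ_idx)


def standardize(values: np.ndarray) -> np.ndarray:
    """Mean-0, sample-SD-1 within the given dataset; missing entries propagate."""
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    if mask.sum() < 2:
        raise DegenerateInputError("need at least 2 non-missing values to standardize")
    sd = np.std(values[mask], ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("zero variance: cannot standardize")
    out = np.full_like(values, np.nan)
    out[mask] = (values[mask] - values[mask].mean()) / sd
    return out


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Whitespace-delimited table with header; first two columns FID, IID."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"], dtype={0: str, 1: str})
    cols = list(df.columns)
    if len(cols) < 3 or cols[0].upper() != "FID" or cols[1].upper() != "IID":
        raise FormatError(f"{path}: expected header starting with FID IID")
    df = df.rename(columns={cols[0]: "FID", cols[1]: "IID"})
    if df.duplicated(subset=["FID", "IID"]).any():
        raise FormatError(f"{path}: duplicated (FID, IID) pairs")
    return df


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_cohort(cohort: Cohort, outdir: str | Path, prefix: str = "cohort") -> None:
    """Emit PLINK genotypes, FID/IID-keyed tables and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(cohort.genotypes, outdir / prefix)
    ids = pd.DataFrame({"FID": cohort.fid, "IID": cohort.iid})
    pheno = ids.copy()
    if cohort.phenotype_qt is not None:
        pheno["pheno_qt"] = cohort.phenotype_qt
    if cohort.phenotype_bt is not None:
        pheno["pheno_bt"] = cohort.phenotype_bt
    write_sample_table(pheno, outdir / f"{prefix}.pheno.txt")
    write_sample_table(pd.concat([ids, cohort.environments.reset_index(drop=True)], axis=1),
                       outdir / f"{prefix}.env.txt")
    if cohort.covariates.shape[1] > 0:
        write_sample_table(pd.concat([ids, cohort.covariates.reset_index(drop=True)], axis=1),
                           outdir / f"{prefix}.covar.txt")
    if cohort.truth is not None:
        serializable = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in cohort.truth.items()
            if not isinstance(v, dict)
        }
        with open(outdir / f"{prefix}.truth.json", "w") as fh:
            json.dump(serializable, fh)


_SUMSTAT_COLS = ["snp", "a1", "beta_add", "se_add", "p_add",
                 "beta_gxe", "se_gxe", "p_gxe", "n"]


def write_sumstats(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in _SUMSTAT_COLS if c not in table.columns]
    if missing:
        raise FormatError(f"summary-statistics table lacks columns {missing}")
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"snp": str, "a1": str})
    missing = [c for c in _SUMSTAT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: summary-statistics table lacks columns {missing}")
    return df
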