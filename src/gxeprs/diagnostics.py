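"""Genomic inflation diagnostics for GWEIS interaction statistics.

Per-SNP chi-square statistics are reconstructed from the exported two-sided
p-values through the 1-df chi-square quantile (exact for the Wald tests the
scan uses).  lambda is the ratio of the median observed statistic to the
null median 0.4549...; lambda_1000 rescales it to a standard sample size of
1000 so studies of different sizes can be compared.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError

__all__ = ["InflationReport", "genomic_inflation", "lambda_1000", "qq_data",
           "inflation_report"]

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.45493642...


def _clean_pvalues(p_values: np.ndarray) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ConfigurationError("no p-values supplied")
    if (p > 1).any() or (p < 0).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 entries clipped to the smallest representable value",
                      stacklevel=3)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p


def genomic_inflation(p_values: np.ndarray) -> float:
    """lambda_GC = median(chi2_1 quantile of 1 - p) / chi2_1 null median."""
    p = _clean_pvalues(p_values)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def lambda_1000(
    lam: float,
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
    n_quantitative: Optional[int] = None,
) -> float:
    """Rescale lambda to a reference sample size of 1000 (1000/1000 for
    case-control designs)."""
    if lam <= 0:
        raise ConfigurationError("lambda must be positive")
    if n_quantitative is not None:
        if n_quantitative <= 0:
            raise ConfigurationError("sample size must be positive")
        return 1.0 + (lam - 1.0) * (1.0 / n_quantitative) / (1.0 / 1000.0)
    if n_cases is None or n_controls is None:
        raise ConfigurationError("supply n_quantitative or both n_cases and n_controls")
    if n_cases <= 0 or n_controls <= 0:
        raise ConfigurationError("case/control counts must be positive")
    return 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)


def qq_data(p_values: np.ndarray) -> np.ndarray:
    """(expected, observed) -log10 p quantile pairs, expected from the
    uniform order statistics (i - 0.5)/n."""
    p = np.sort(_clean_pvalues(p_values))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return np.column_stack([expected, observed])


@dataclass
class InflationReport:
    lambda_gc: float
    lambda_1000: Optional[float]
    n_tests: int
    n_effective: dict
    qq_points: np.ndarray


def inflation_report(
    p_values: np.ndarray,
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
    n_quantitative: Optional[int] = None,
) -> InflationReport:
    lam = genomic_inflation(p_values)
    lam1000 = None
    if n_quantitative is not None or (n_cases is not None and n_controls is not None):
        lam1000 = lambda_1000(lam, n_cases=n_cases, n_controls=n_controls,
                              n_quantitative=n_quantitative)
    p = _clean_pvalues(p_values)
    return InflationReport(
        lambda_gc=lam,
        lambda_1000=lam1000,
        n_tests=int(p.size),
        n_effective={"n_cases": n_cases, "n_controls": n_controls,
                     "n": n_quantitative},
        qq_points=qq_data(p_values),
    )
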