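"""Shared fixtures: small simulated cohorts and pipeline products."""
from __future__ import annotations

import numpy as np
import pytest

import gxeprs as gx
from gxeprs.io import SplitSpec, split_cohort, standardize


@pytest.fixture(scope="session")
def qt_cohort():
    """Quantitative cohort with real GxE signal, split 8:2."""
    cfg = gx.SimConfig(
        n_individuals=2500, n_snps=400, n_envs=3,
        env_correlation=np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]]),
        var_additive=0.3, var_env_main=0.05, var_gxe=0.05,
        covariate_spec=(("sex", 0.1), ("age", 0.2)),
        seed=42,
    )
    cohort = gx.simulate_cohort(cfg, kinds=["quantitative", "binary"])
    disc, targ = split_cohort(cohort, SplitSpec(seed=42))
    return cohort, disc, targ


@pytest.fixture(scope="session")
def qt_analysis(qt_cohort):
    """GWEIS -> PRS -> full/reduced target fits for the first environment."""
    _, disc, targ = qt_cohort
    e_d = standardize(disc.environments["env0"].to_numpy())
    e_t = standardize(targ.environments["env0"].to_numpy())
    y_adj = gx.adjust_phenotype_qt(disc.phenotype_qt, disc.covariates)
    gweis = gx.run_gweis_qt(disc.genotypes, y_adj, e_d, env_name="env0")
    pair = gx.compute_prs_pair(targ.genotypes, gweis)
    full = gx.fit_gxeprs_qt(targ.phenotype_qt, pair, e_t, covariates=targ.covariates)
    reduced = gx.fit_gxeprs_qt(targ.phenotype_qt, pair, e_t,
                               covariates=targ.covariates, reduced=True)
    return {"disc": disc, "targ": targ, "e_d": e_d, "e_t": e_t,
            "gweis": gweis, "pair": pair, "full": full, "reduced": reduced}
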