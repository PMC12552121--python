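"""End-to-end orchestration of the three analysis phases.

Phase I analyses each outcome with one environmental variable at a time:
GWEIS in the discovery set, PRS construction in the target set, the full /
reduced target models, the nested-model comparison, the permutation
companion test, and inflation diagnostics.  Phase II repeats the target-side
analysis with composite exposures (sum_dir and PC1).  Phase III pools the
per-environment model components from Phase I and runs forward AIC
selection.  Significance is reported with a Bonferroni threshold over the
number of analyses in the phase, both exact (0.05/m) and rounded to one
significant figure as conventionally printed.
"""
from __future__ import annotations

import json
import math
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composite import make_pc1, make_sum_dir
from .containers import Cohort
from .evaluate import auc_diff_test, r2_diff_test
from .exceptions import ConfigurationError, DegenerateInputError, GxeprsError
from .diagnostics import genomic_inflation, lambda_1000
from .gweis import adjust_phenotype_qt, run_gweis_bt, run_gweis_qt
from .io import SplitSpec, split_cohort, standardize
from .prs import compute_prs_pair
from .simulate import SimConfig, simulate_cohort
from .stepwise import build_pool, forward_select
from .target import fit_gxeprs_bt, fit_gxeprs_qt, permute_interaction

__all__ = ["PhasePlan", "bonferroni_threshold", "analyze_pair", "run_phase",
           "run_study"]


def _round_sig(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def bonferroni_threshold(n_analyses: int) -> tuple[float, float]:
    """(exact, printed) family-wise 0.05 threshold: 0.05/101 prints as
    0.0005 and 0.05/26 as 0.002."""
    if n_analyses <= 0:
        raise ConfigurationError("analysis count must be positive")
    exact = 0.05 / n_analyses
    return exact, _round_sig(exact, 1)


@dataclass
class PhasePlan:
    """What one phase runs and how its multiplicity is accounted."""

    phase: str                      # "I" | "II" | "III"
    outcomes: Sequence[str]         # subset of ("quantitative", "binary")
    environments: Sequence[str]
    analysis_count: Optional[int] = None
    composite_methods: Sequence[str] = ("sum_dir", "PC1")
    directions: Optional[dict] = None
    prevalence: Optional[float] = None
    seed: int = 0
    permute: bool = False
    min_perm: int = 1000
    max_perm: int = 10_000

    def __post_init__(self) -> None:
        if self.phase not in ("I", "II", "III"):
            raise ConfigurationError(f"unknown phase {self.phase!r}")
        if not self.outcomes:
            raise ConfigurationError("phase plan lists no outcomes")
        bad = set(self.outcomes) - {"quantitative", "binary"}
        if bad:
            raise ConfigurationError(f"unknown outcome kinds: {sorted(bad)}")

    @property
    def bonferroni(self) -> tuple[float, float]:
        m = self.analysis_count
        if m is None:
            per = len(self.environments) if self.phase != "II" else len(self.composite_methods)
            m = len(self.outcomes) * per
        return bonferroni_threshold(m)


def _phenotype(cohort: Cohort, kind: str) -> np.ndarray:
    y = cohort.phenotype_qt if kind == "quantitative" else cohort.phenotype_bt
    if y is None:
        raise ConfigurationError(f"cohort has no {kind} phenotype")
    return y


def analyze_pair(
    discovery: Cohort,
    target: Cohort,
    outcome_kind: str,
    env_disc: np.ndarray,
    env_targ: np.ndarray,
    env_name: str,
    prevalence: Optional[float] = None,
    permute: bool = False,
    seed: int = 0,
    min_perm: int = 1000,
    max_perm: int = 10_000,
):
    """One outcome/environment analysis: GWEIS -> PRS -> target models ->
    nested comparison (-> permutation).  Returns (summary dict, PRSPair)."""
    y_disc = _phenotype(discovery, outcome_kind)
    y_targ = _phenotype(target, outcome_kind)
    if outcome_kind == "quantitative":
        y_adj = adjust_phenotype_qt(y_disc, discovery.covariates)
        gweis = run_gweis_qt(discovery.genotypes, y_adj, env_disc, env_name=env_name)
    else:
        gweis = run_gweis_bt(discovery.genotypes, y_disc, env_disc,
                             covariates=discovery.covariates, env_name=env_name)
    pair = compute_prs_pair(target.genotypes, gweis)

    covar = target.covariates if target.covariates.shape[1] else None
    if outcome_kind == "quantitative":
        full = fit_gxeprs_qt(y_targ, pair, env_targ, covariates=covar)
        red = fit_gxeprs_qt(y_targ, pair, env_targ, covariates=covar, reduced=True)
        comp = r2_diff_test(full, red)
    else:
        full = fit_gxeprs_bt(y_targ, pair, env_targ, covariates=covar)
        red = fit_gxeprs_bt(y_targ, pair, env_targ, covariates=covar, reduced=True)
        comp = auc_diff_test(full, red, prevalence=prevalence)

    p_gxe = gweis.table.loc[gweis.table["estimable"], "p_gxe"].to_numpy()
    lam = genomic_inflation(p_gxe)
    if outcome_kind == "quantitative":
        lam1000 = lambda_1000(lam, n_quantitative=int(gweis.table["n"].iloc[0]))
    else:
        n_case = int(np.nansum(y_disc))
        lam1000 = lambda_1000(lam, n_cases=n_case,
                              n_controls=int((y_disc == 0).sum()))

    summary = {
        "env": env_name,
        "outcome_kind": outcome_kind,
        "n_discovery": discovery.n,
        "n_target": full.n,
        "alpha": {k: float(v) for k, v in full.params.items()},
        "alpha_se": {k: float(v) for k, v in full.se.items()},
        "alpha_p": {k: float(v) for k, v in full.p.items()},
        "p_gxe_component": float(full.p.get("x_gxe_x_E", np.nan)),
        "metric_full": comp.metric_full,
        "metric_reduced": comp.metric_reduced,
        "delta": comp.delta,
        "p_delta": comp.p_delta,
        "var_gxe_observed": comp.var_gxe_observed,
        "var_gxe_liability": comp.var_gxe_liability,
        "lambda_gc": lam,
        "lambda_1000": lam1000,
    }
    if permute:
        perm = permute_interaction(full, seed=seed, min_perm=min_perm,
                                   max_perm=max_perm)
        summary["permutation"] = {
            "p_perm": perm.p_perm,
            "n_perm": perm.n_perm,
            "observed_stat": perm.observed_stat,
            "p_asymptotic": perm.p_asymptotic,
        }
    return summary, pair


def _standardized_envs(cohort: Cohort, required: bool = False) -> pd.DataFrame:
    """Standardize each exposure within the dataset; degenerate columns become
    all-NaN unless ``required`` (they then fail inside the per-pair guard)."""
    cols = {}
    for c in cohort.environments.columns:
        vals = cohort.environments[c].to_numpy(dtype=float)
        try:
            cols[c] = standardize(vals)
        except DegenerateInputError:
            if required:
                raise
            cols[c] = np.full(len(vals), np.nan)
    return pd.DataFrame(cols)


def run_phase(plan: PhasePlan, discovery: Cohort, target: Cohort) -> dict:
    """Execute one phase; stage failures are recorded per pair, the phase
    continues for the remaining pairs."""
    t0 = time.time()
    envs_disc = _standardized_envs(discovery)
    envs_targ = _standardized_envs(target)
    exact, printed = plan.bonferroni
    report: dict = {
        "phase": plan.phase,
        "bonferroni_exact": exact,
        "bonferroni_printed": printed,
        "seed": plan.seed,
        "version": __version__,
        "pairs": {},
        "errors": {},
    }

    def _record(key: str, fn):
        try:
            report["pairs"][key] = fn()
        except GxeprsError as exc:
            report["errors"][key] = f"{type(exc).__name__}: {exc}"

    prs_cache: dict[tuple[str, str], object] = {}
    if plan.phase in ("I", "III"):
        for kind in plan.outcomes:
            for env_name in plan.environments:
                def _run(kind=kind, env_name=env_name):
                    summary, pair = analyze_pair(
                        discovery, target, kind,
                        envs_disc[env_name].to_numpy(),
                        envs_targ[env_name].to_numpy(),
                        env_name,
                        prevalence=plan.prevalence if kind == "binary" else None,
                        permute=plan.permute and plan.phase == "I",
                        seed=plan.seed,
                        min_perm=plan.min_perm, max_perm=plan.max_perm,
                    )
                    prs_cache[(kind, env_name)] = pair
                    return summary
                _record(f"{kind}/{env_name}", _run)
    if plan.phase == "II":
        directions = plan.directions or {c: 1 for c in envs_disc.columns}

        def _composite(name):
            if name == "sum_dir":
                return (make_sum_dir(envs_disc, directions).values,
                        make_sum_dir(envs_targ, directions).values)
            return (make_pc1(envs_disc).values,
                    make_pc1(envs_disc, envs_targ, fitted_on="discovery").values)

        for kind in plan.outcomes:
            for name in plan.composite_methods:
                def _run(kind=kind, name=name):
                    e_disc, e_targ = _composite(name)
                    summary, _ = analyze_pair(
                        discovery, target, kind, e_disc, e_targ, name,
                        prevalence=plan.prevalence if kind == "binary" else None,
                        permute=plan.permute, seed=plan.seed,
                        min_perm=plan.min_perm, max_perm=plan.max_perm,
                    )
                    return summary
                _record(f"{kind}/{name}", _run)
    if plan.phase == "III":
        for kind in plan.outcomes:
            def _run(kind=kind):
                prs_per_env = {e: prs_cache[(kind, e)] for e in plan.environments
                               if (kind, e) in prs_cache}
                if len(prs_per_env) != len(plan.environments):
                    raise ConfigurationError("missing Phase I PRS for some environments")
                pool = build_pool(prs_per_env, envs_targ[list(plan.environments)], kind)
                covar = target.covariates if target.covariates.shape[1] else None
                sel = forward_select(_phenotype(target, kind), pool, covariates=covar,
                                     outcome_kind=kind)
                return {
                    "pool_size": pool.size,
                    "selected": sel.selected,
                    "aic_trace": sel.aic_trace,
                    "base_aic": sel.base_aic,
                    "final_metric": sel.final_fit.fit_metric,
                    "final_metric_name": sel.final_fit.metric_name,
                    "final_p": {k: float(v) for k, v in sel.final_fit.p.items()},
                    "dropped": sel.dropped,
                }
            _record(f"{kind}/stepwise", _run)
    report["elapsed_s"] = time.time() - t0
    return report


def run_study(config: dict, outdir: Optional[Path] = None, seed: int = 0) -> dict:
    """Simulate a cohort per ``config``, split it 8:2, and run the requested
    phases; optionally write per-phase JSON reports."""
    sim_cfg = dict(config.get("simulate", {}))
    n_envs = int(sim_cfg.get("n_envs", 1))
    offdiag = sim_cfg.pop("env_correlation_offdiag", None)
    if offdiag is not None and "env_correlation" not in sim_cfg:
        corr = np.full((n_envs, n_envs), float(offdiag))
        np.fill_diagonal(corr, 1.0)
        sim_cfg["env_correlation"] = corr
    sim_cfg.setdefault("seed", seed)
    outcomes = list(config.get("outcomes", ["quantitative"]))
    cohort = simulate_cohort(SimConfig(**sim_cfg), kinds=outcomes)

    split = config.get("split", {})
    spec = SplitSpec(discovery_fraction=float(split.get("discovery_fraction", 0.8)),
                     seed=int(split.get("seed", seed)))
    discovery, target = split_cohort(cohort, spec)

    env_names = list(cohort.environments.columns)
    perm_cfg = config.get("permutation", {})
    prevalence = float(sim_cfg.get("prevalence", 0.1))
    results: dict = {"seed": seed, "n_discovery": discovery.n, "n_target": target.n}
    for phase in config.get("phases", ["I"]):
        plan = PhasePlan(
            phase=phase,
            outcomes=outcomes,
            environments=env_names,
            directions=config.get("directions"),
            prevalence=prevalence,
            seed=seed,
            permute=bool(perm_cfg.get("enabled", phase == "I")),
            min_perm=int(perm_cfg.get("min_perm", 1000)),
            max_perm=int(perm_cfg.get("max_perm", 10_000)),
        )
        results[f"phase_{phase}"] = run_phase(plan, discovery, target)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "study.json", "w") as fh:
            json.dump(results, fh, indent=2, default=_json_default)
    return results


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
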