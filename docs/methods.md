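# Methods

This note documents the models, estimators, defaults and numerical choices
behind `gxeprs`, and what the synthetic-data experiments do and do not show
about real data.

## Generative model

A cohort is simulated as independent biallelic SNPs, correlated Gaussian
exposures, and phenotypes with a controlled variance decomposition.

**Genotypes.** Per SNP, an allele frequency f is drawn uniformly on
`maf_range` (default 0.05–0.5) and hard-call dosages are two Bernoulli(f)
draws (so dosage ~ Binomial(2, f)). There is deliberately no linkage
disequilibrium: every SNP is independent, which keeps PRS construction free
of clumping concerns and makes variance targeting exact. Missing calls are
injected only on request (default 0%).

**Exposures.** `n_envs` exposures are multivariate Gaussian with a
user-specified correlation matrix (unit diagonal, PSD enforced via
eigendecomposition when the Cholesky fails on a semidefinite input). They
are returned unstandardised; standardisation is a pipeline step applied
*within* each of the discovery and target datasets, mirroring how exposures
are handled in the analysis itself.

**Phenotypes.** With g̃_j the dosage centred and scaled by
`sqrt(2 f_j (1-f_j))` (the sampled population frequency — missing calls
contribute the population mean, i.e. 0 after centring):

    y = Σ_j β_j g̃_j + γ E + Σ_j δ_j g̃_j E + Σ_c w_c C_c + ε

β and δ are i.i.d. Gaussian on their causal subsets, then rescaled so that
Σβ² = `var_additive` and Σδ² = `var_gxe` exactly; γ = sqrt(`var_env_main`);
ε is Gaussian with variance 1 − (sum of the three fractions), which must be
positive. Because g̃ and E are independent with unit variance, each
component contributes its configured fraction of the unit-variance
genetic+environmental+residual core in expectation. Covariate effects add
variance *on top* of that core, so the fractions describe the
covariate-adjusted phenotype. The additive-causal and interaction-causal
SNP sets fully overlap by default (`causal_overlap=True`); a disjoint
layout is available.

**Binary traits.** The identical continuous construction serves as a
liability; a case is `liability > Phi^-1(1 - K) * sd(liability)` with the
*theoretical* SD (`sqrt(1 + Σ w_c²)`), keeping prevalence K a population
parameter rather than a sample quantile. As K → 1 the threshold falls below
any liability and the generator degenerates to all cases, as it should.
Note one deliberate consequence: the liability is not exactly Gaussian —
the GxE term is a product of Gaussians (leptokurtic). This matters for
liability-scale estimation (below).

## Discovery stage (GWEIS)

Quantitative traits are first residualised on intercept + covariates
(`adjust_phenotype_qt`); the scan then fits, per SNP, OLS of the residual on
{1, g, E, g·E}. The per-SNP normal equations are assembled for all SNPs at
once from eight matrix products, so the scan is a handful of BLAS calls
rather than a Python loop. The E main effect stays in every per-SNP model
(omitting it would bias the interaction estimate) but only the g and g·E
coefficients are exported. Binary traits keep covariates inside each
per-SNP model — logistic residualisation is not exact — and add an E²
term guarding against main-effect misspecification; each SNP is fitted by
Newton/IRLS with a score-norm tolerance of 1e-8 and at most 50 iterations.
Non-convergence (e.g. separation) and monomorphic SNPs are flagged
per SNP, never silently dropped. Missing dosages are mean-imputed per SNP;
rows missing the outcome or exposure are dropped listwise.

Model-based (non-robust) standard errors are used throughout; the
consequence under heteroskedasticity is quantified only by the calibration
suite, and a sandwich option is out of scope.

## Scores and target models

PRSs use every estimable SNP — no p-value thresholding or clumping, since
simulated SNPs are independent (a threshold flag exists but defaults off).
Alleles are aligned by identifier and allele pair; an effect reported for
the other allele flips sign; irreconcilable or (optionally) palindromic
SNPs are excluded. Both scores are standardized within the target set so
the target-model coefficients are scale-comparable; this choice is recorded
on the `PRSPair`.

The target models are as in the README. The permutation companion permutes
*only* the X̂_gxe⊙E column and refits the full model each time — an exact
scheme at desk scale, preserving the joint distribution of the outcome with
every other column. The permutation count is
`B = max(1000, ceil(100 / p_asymptotic))`, capped (default 10^6 in the
library, smaller caps in the orchestrated runs), so near a decision boundary
roughly 100 exceedances are expected; p uses the add-one estimator
`(1 + #exceed) / (1 + B)` and is therefore never zero. Requests below 1000
are raised to the floor.

## Nested-model evaluation

**Quantitative.** Var(GxE) is ΔR² = R²_full − R²_reduced. Its sampling SE
comes from the delta method over the joint distribution of the two
model-fit correlations (Pearson–Filon/Steiger covariance). That variance,
however, degenerates to zero for exactly nested models under the null (the
two fitted scores become perfectly correlated), so the *reported* `p_delta`
is the exact one-degree-of-freedom partial-F test; the delta-method normal
p is kept alongside as `p_delta_asymptotic`, and the suite checks the two
agree in rank across replicate datasets.

**Binary.** ΔAUC between the two models' fitted probabilities is tested
with the paired DeLong procedure (placement-value covariance with
midranks). Liability-scale Var(GxE) is estimated two ways:

- *Primary:* a single probit companion refit of the **full** design.
  Because the residual liability is Gaussian, the conditional model of the
  outcome given the predictors is exactly probit, so the fitted latent
  predictor η̂ (in residual-SD units) is consistent even though the
  X̂_gxe⊙E column is leptokurtic. The reduced model's explained latent
  variance is the linear projection of η̂ onto the reduced columns — a
  reduced probit *refit* would itself be misspecified (its omitted
  component is not Gaussian residual) and measurably biases the difference.
  Var(GxE) = (var(η̂) − var(proj η̂)) / (var(η̂) + 1), floored at 0. The
  per-model McKelvey–Zavoina latent R², `var(η̂)/(var(η̂)+1)`, is exposed
  as a utility. This route assumes a population sample (no case-control
  ascertainment).
- *Companion:* the AUC route, `AUC → d = sqrt(2) Phi^-1(AUC) →`
  point-biserial observed-scale R² at case fraction P `→` liability R² by
  the standard K,P transformation, differenced and floored at 0. This route
  assumes binormal equal-variance scores; under the generative model above
  it under-recovers Var(GxE) by roughly a tenth (the product component
  violates binormality), which is why it is not the primary estimator. It
  is exposed as `var_gxe_liability` / `var_gxe_liability_auc` for settings
  where only AUCs are available.

Negative liability differences (possible since in-sample AUC of a nested
logistic model can decrease) are floored at zero with a warning.

## Composites and stepwise selection

`sum_dir` adds standardized exposures with user-declared ±1 signs (in the
motivating design: healthy-diet and physical-activity positive, the rest
negative, oriented toward healthy lifestyle), then re-standardizes.
`PC1` uses the leading eigenvector of the exposure covariance as weights,
fitted on the *discovery* set and applied unchanged to the target — fitting
on discovery prevents target-set leakage into the weights; the alternative
per-dataset refit is available by calling `make_pc1` on each set. The
eigenvector sign is fixed deterministically (largest-|loading| positive).

Phase III pools, per environment, X̂_add, X̂_gxe, E and X̂_gxe⊙E (plus E²
for binary outcomes; 4 or 5 columns per environment) and runs forward
selection by AIC (= −2·loglik + 2·k, k counting all coefficients including
the intercept) from a covariates-only base model. Covariates are forced and
never candidates; E main effects are ordinary candidates. Collinear
candidates are skipped with a warning; AIC ties break lexicographically by
component name so the path is deterministic across platforms. As published,
selection and evaluation share the target set — an acknowledged optimism
source; the `stepwise` CLI offers a `--split-half` mode (select on a random
half, evaluate the chosen model on the other half) as the honest
alternative.

## Diagnostics

λ is the median of the per-SNP 1-df chi-square statistics (reconstructed
from two-sided p-values via the chi-square quantile — exact for Wald tests)
divided by 0.4549; λ₁₀₀₀ rescales to a standard sample size of 1000
(`1 + (λ−1)·(1/n_cases + 1/n_controls)/(2/1000)` for case-control,
`1 + (λ−1)·(1/n)/(1/1000)` for quantitative). QQ data pair sorted observed
−log₁₀ p with uniform order-statistic expectations `(i − 0.5)/n`; zero
p-values are clipped to the smallest representable double with a warning.
The theoretical inflation factor of external derivation is not implemented.

## Orchestration, sizes and reproducibility

The three phases run from a single config; Bonferroni thresholds are
reported exact (0.05/m) and rounded to one significant figure as
conventionally printed (0.05/101 → 0.0005, 0.05/26 → 0.002). All
randomness flows through explicit integer seeds (`numpy` Generator); fixed
seeds reproduce cohorts and all downstream numerics bit-for-bit on a given
platform (cross-platform BLAS differences may perturb the last few ulps of
fitted coefficients).

Problem sizes used by the experiments shipped with the package (chosen as
desk-scale stand-ins for a biobank analysis): type-I calibration at
n = 5,000 individuals × 2,000 SNPs × 500 replicates with var_gxe = 0;
quantitative Var(GxE) recovery at n = 20,000 × 50 replicates with
var_gxe = 0.01; binary liability recovery at n = 50,000, K = 0.2,
var_gxe = 0.03; the acceptance study at n = 6,000 × 1,200 SNPs with three
correlated exposures. Recovery experiments use the truth-record component
scores, isolating the evaluator from discovery-stage estimation noise.

## Limitations

- No LD, no imputation dosages, no relatedness/mixed models, no X
  chromosome: the generator emulates the statistical structure of the
  analysis, not the correlation structure of a real genome. Passing tests
  show the estimators are correct under the stated model, not that a real
  cohort's QC pipeline is reproduced.
- Liability-scale conversion assumes a population sample; case-control
  ascertainment would require the full Lee-style adjustment of the primary
  estimator.
- In-sample evaluation (same target set for fitting and metrics) is
  reproduced as published and is optimistic; prefer the split-half mode for
  honest prediction claims.
- Exposure distributions are Gaussian by construction; real exposures are
  skewed, zero-inflated and measured with error, all of which attenuate
  GxE signal in ways the simulations do not capture.
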