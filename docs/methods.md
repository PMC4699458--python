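# Methods

## The data model

All stages operate on a long-format table: one row per (subject, visit)
with a group label (`ART-Def`, `ART-Early`, `HEU`), visit age in days,
ART initiation day, and 17 measurement columns — birth weight (g), CD4%
(its own assay panel, always observed), 12 flow-cytometry percentages
plus CD38 MFI (one 13-variable flow panel), serum IL-7 (ELISA,
detection range 0.25–16 pg/mL), and log10 viral load. A missing cell is
an empty CSV field / NaN; the boolean mask is derived from it, so mask
and values can never disagree.

## Synthetic cohort generator

The generator emulates the structure the downstream estimators assume,
calibrated to published per-(group, visit) means and SDs.

**Bounded marginals.** Each variable is drawn through a Gaussian copula:
correlated standard normals (exchangeable ρ = 0.3 within the T-cell
panel, independent elsewhere) are mapped through each variable's
truncated normal (censored normal for the detection-limited ELISA). The
latent (μ, σ) are moment-matched so the *post*-truncation mean equals the
printed target exactly (1-D monotone solve in μ nested in a 1-D solve in
σ for the SD). Near a bound the truncated-normal coefficient of variation
is capped; for the handful of strongly skewed cells (e.g. pDC ≈ 0.2 ±
0.3%) the printed SD is unattainable by any truncated normal, so σ is
capped and the achieved SD is the closest feasible — the mean is still
exact. Percentages stay strictly inside (0, 100); the real assays never
report exact 0 or 100 either.

**Geometry.** Visit-2 subjects are a prefix subset of visit-1 subjects
(retention nesting); birth weight is drawn once per subject; ART
initiation days are log-normal with (μ, σ) matched to the printed
median/IQR by quantile matching (positive, right-skewed, three printed
quantiles — two parameters, median matched exactly). Visit ages are
truncated normal per group/visit.

**Missingness injection.** Masking is panel-level by default — the
documented failure mode is a failed or insufficient blood draw, which
removes an entire assay panel at that visit. MCAR masks each panel-record
independently at the target rate. MAR masks with probability
logistic(α + slope·driver) where the driver is a fully observed variable
and α is calibrated by root-finding so the realized marginal rate equals
the target. MNAR is necessarily cell-level (each variable's own
standardized value is its driver). CD4%, birth weight and the metadata
are never maskable.

**The packaged fixture** uses seed 20151215 and reproduces the published
"tests available" counts exactly: per (group, visit, panel) the number of
masked records equals the published observed-n deficit, with visit-1
masking allocated between both-visit and single-visit subjects so the
longitudinal missingness map shows the published ≈31% flow / ≈20% ELISA
rates (21/68 and 14/68 records).

**What the generator does not emulate:** skewed/heteroscedastic assay
noise (marginals are symmetric up to truncation), subject-level random
effects linking visits beyond the shared latent correlation, informative
visit timing, and measurement error in CD4%. Passing calibration and
coverage tests on this cohort therefore establishes correctness of the
*estimators under their stated assumptions*, not robustness to every
feature of real cytometry data.

## EM for the incomplete multivariate normal

Rows are grouped by missingness pattern. For a pattern with observed set
O and missing set M, the E-step fills E[x_M | x_O] = μ_M +
Σ_MO Σ_OO⁻¹ (x_O − μ_O) and accumulates the conditional covariance
Σ_MM − Σ_MO Σ_OO⁻¹ Σ_OM into the second-moment statistics; the M-step is
the closed-form Gaussian MLE with denominator n. Convergence is declared
when the observed-data log-likelihood moves by less than `tol` (default
1e-6, `max_iter` 500 — the source analyses name no tolerances; these
match common defaults for this model class). The log-likelihood is
checked to be non-decreasing at every iteration and a decrease raises.
Rows with no observed cells are dropped from estimation with a warning;
a covariance eigenvalue below 1e-8 triggers a diagonal ridge and flags
the fit. Starting values are the available-case means and diagonal
variances.

An optional `prior_scale` adds a diagonal ridge prior to the M-step,
Σ = (SS + λ·diag(available-case variances)) / (n + λ). It is off by
default (the MLE contract above) and used by the bootstrap-EM imputer
only as a fallback when a degenerate resample (few distinct rows
relative to p) makes the MLE singular; with the prior active the
monotonicity guarantee is on the penalized objective, so only the
convergence criterion applies.

`disperse_check` reruns EM from k over-dispersed starts (available-case
moments perturbed, covariance inflated ×4 by default) and reports
whether all runs agree in final log-likelihood and parameters — the
standard visual EM-convergence diagnostic, made programmatic.

## Little's MCAR test

d² = Σ_J n_J (ȳ_J,obs − μ̂_O_J)ᵀ Σ̂_O_J O_J⁻¹ (ȳ_J,obs − μ̂_O_J) with
(μ̂, Σ̂) the EM MLE, referred to χ² with df = Σ_J p_J − p. Fully observed
variables are included in every pattern's observed set — they sharpen the
grand-parameter estimate. Patterns with zero observed variables are
excluded; a single pattern (complete data) yields d² = 0, df = 0, p = 1
flagged inapplicable; any pattern with fewer than 5 cases triggers a
small-sample warning. The statistic is affine-invariant, so assay scale
is irrelevant.

Calibration at the study's scale (n = 100, p = 6, two 3-variable panels
masked MCAR at 30%): empirical size ≈ 0.04–0.05 at α = 0.05 over 1000
replicates. Power against self-masking (two 2-variable panels driven by
their own lead variable, marginal rate 0.3) rises from α at slope 0 to
≈0.8 at slope 1·SD and ≈0.99 at slope 2·SD at n = 300; n = 300 is used
for the power experiment because the test's power at slope 1 sits almost
exactly at 1/2 at n = 200. Note the test has essentially *no* power when
every variable is self-masked — all pattern means shift together — which
is a known blind spot of this statistic, not an implementation artifact.

## Multiple imputation (bootstrap-EM)

Each of m imputations (default 5, the usual recommendation for
moderate missingness) resamples rows with replacement, runs EM on the
resample, and draws every incomplete row's missing block from its
conditional Gaussian under those bootstrap parameters — parameter
uncertainty enters through the bootstrap, draw uncertainty through the
conditional. The imputation model is the joint normal over all
measurement columns plus a numeric arm code and visit age (constant
extras are dropped). Observed cells are never modified (asserted by
hash in the tests). Imputed values outside a variable's bounds are
clipped and counted; a clipping rate above 2% escalates a warning (the
packaged fixture sits near 6% — dominated by variables whose printed SD
already exceeds the truncated-normal cap, e.g. pDC and NK subsets — and
the warning is the designed behavior, not an error).

**Overimputation.** Each observed cell of a chosen variable is treated
as missing in turn; `draws_per_cell` (20) bootstrap-EM parameter sets
are fitted once, each contributing a conditional normal for the cell.
The 90% interval is the exact 5th–95th quantile of that equal-weight
normal mixture (bisection on the mixture CDF) — *not* the empirical
percentile of 20 point draws, which is systematically narrow and
undercovers by ~8 points. Under a correctly specified MVN model at
n = 300 the realized coverage is ≈0.90.

**Rubin's rules.** Q̄ = mean(Q_i), Ū = mean(SE_i²), B = var(Q_i, ddof 1),
T = Ū + (1 + 1/m)B, df = (m − 1)(1 + Ū/((1+1/m)B))², t = Q̄/√T. B = 0
(identical fits — e.g. a fully observed response) degenerates the df
formula; the complete-data residual df is substituted and flagged, and a
vanishing-but-nonzero B is capped at df 1e12 to avoid overflow.

## Frequentist models

Baseline two-group comparisons use Welch's unequal-variance t from
summary statistics (the pooled-variance form does not reproduce the
published p-values from the published means/SDs/n; Welch does, to
printed precision). The Bonferroni family is all 17 baseline rows
(α/17 ≈ 0.00294 — the only family size consistent with the published
significance pattern, which flags 0.0027 but not 0.0035).

Arm-effect GLMs: `normal-identity` is OLS with classical SEs (with one
binary covariate the arm coefficient is exactly the group-mean
difference). `poisson-log` is quasi-Poisson IRLS — the responses are
continuous, so a genuine Poisson likelihood is improper and the Pearson
χ²/df dispersion scales the SEs. Two codings of a percentage response:
`percent` (default) fits 100·proportion directly, under which the
log-link arm coefficient equals the log ratio of fitted group means
(this is the coding that reproduces the published Poisson-scale
estimates, e.g. ln(38.27/33.93) = 0.120); `log100` fits
ln(100·proportion) literally and is kept as an option (it cannot
reproduce those estimates, and produces negative responses for
sub-1% variables like pDC — configurable shift-or-error handling).

Stepwise logistic selection (arm as outcome) prunes candidates by
backward greedy AIC within each imputed dataset; the final set is the
variables retained in more than half the imputations (majority vote —
the interaction of stepwise selection with multiple imputation is
underdetermined in the source description, and this is the package's
documented choice), refit per imputation and Rubin-pooled. Separation
is detected and stabilized with a small ridge.

## One-step Bayesian models

The "one-step" model treats missing *responses* as extra unknowns
sampled jointly with the parameters; covariates (arm, visit, age) are
complete by design, matching the univariate arm-effect models.

*Normal likelihood*: conjugate Gibbs. β ~ N(0, τ²I) with τ = 10 ×
SD(observed response) — the closest reproducible reading of "priors
derived from observed data": weakly informative, scales with the
response, centered at no effect. σ² ~ InvGamma(0.001, 0.001). Each sweep
draws missing responses from N(x'β, σ²), then β and σ² from their full
conditionals including the augmented rows (valid data augmentation; the
marginal posterior for β equals the observed-data posterior). An
explicit `prior_sd` and a `fixed_sigma2` (known-variance) mode exist for
conjugate closed-form verification.

*Poisson likelihood*: responses are rounded percent-scale counts (the
natural way to feed continuous percentages to a count likelihood).
Coefficients move by joint random-walk Metropolis on the observed-data
posterior, with the proposal scale adapted during burn-in toward 20–40%
acceptance; missing responses are drawn as Poisson(exp(x'β)) for
imputation output but do not feed back into the β update — rows with
missing response and complete covariates carry no likelihood information
about β, so this targets the identical posterior with less work.

Defaults: 2 chains with over-dispersed starts, burn-in 4000 (a
conservative fixed burn-in), n_iter 10⁵ (the pipeline default is 10⁴,
which the recovery experiments show is ample for these small conjugate
models). R-hat is the between/within variance ratio
√(1 + (1+1/m)·B_n/W) — written without the (n−1)/n deflation so that
identical chains give exactly 1.0 and R̂ ≥ 1 always; at n ≥ 10⁴ retained
draws it differs from the split-R̂ variant by O(10⁻⁴). R-hat > 1.1 flags
the fit non-converged. ESS uses the autocorrelation sum with Geyer's
initial-positive-pair truncation. DIC = D̄ + p_D, p_D = D̄ − D(θ̄), with
deviance over observed rows; in the diffuse-prior normal linear model
p_D lands within a few percent of the sampled-parameter count
(coefficients + variance). Wald-style two-sided p-values from posterior
mean/SD against a normal reference are reported alongside the credible
intervals, mirroring the source's significance convention.

Fewer than 10 observed responses triggers a prior-sensitivity warning
rather than an error (the conjugate verification examples use 4).

## Pipeline and concordance

`run_pipeline` executes simulate → diagnose (map + Little per visit and
stacked) → MI (m = 5) → pooled GLMs (normal + Poisson) → Bayesian fits
(normal + Poisson) → concordance, and is bit-reproducible under a master
seed. A stage failure marks the stage and skips dependents. Concordance
is the OLS line and Pearson r between two 15-variable estimate vectors;
because the axis choice is underdetermined (difference estimates vs
predicted means; raw vs log) it is computed for both columns and, where
positive, the log transform — the headline comparison is the arm-effect
(difference) column untransformed. On the fixture the MI-vs-Bayes normal
R² is ≈1.0 (both estimate the same linear contrast; the MFI variable's
scale dominates the regression). The normal-vs-Poisson sensitivity
comparison per method is recorded in every report but deliberately not
asserted — which method is more distribution-sensitive is a data-set
property, not a package invariant.

## Recovery experiment (calibration at the study's geometry)

200 replicates draw the published arm geometry (24/42 at visit 1, 12/22
retained), inject a +4 percentage-point visit-2 arm effect on a
percent-scale flow response, and mask the flow panel MCAR at 31%. The
analysis is on the visit-2 rows of both-visit subjects (12 + 22): MI is
imputed *within the analysis visit* — the injected effect exists only at
visit 2, so a cross-visit joint-normal imputation model is misspecified
for it and attenuates the estimate by ~0.6 points; per-visit imputation
removes that bias — then pooled; the Bayesian normal model augments the
~31% missing responses directly. Both 95% intervals cover the true
effect in 90–98% of replicates with |bias| well under 0.5 points.

## Problem sizes

The shipped experiments use sizes chosen to estimate each operating
characteristic to useful precision: 1000 replicates for test size
(binomial SE ≈ 0.7 points), 100–150 per power point, 200 for interval
coverage (SE ≈ 1.5 points), n = 300 cells for overimputation coverage,
10⁴ MCMC iterations with burn-in 4000 for pipeline fits. All experiment
entry points take explicit seeds and replicate counts.

## Known limitations

- The imputation model is a single joint normal; bounded variables are
  imputed on the raw scale and clipped, which slightly biases cells whose
  mass sits against a bound (pDC, NK immature, CD38%).
- Skewed printed SDs near bounds cannot be matched by truncated normals
  (SD capped, mean exact); affected generator cells are listed by the
  moment-matching tests.
- Little's test is blind to MNAR mechanisms that shift all variables'
  pattern means together.
- Quasi-Poisson and rounded-count Poisson are pragmatic devices for
  percentage data, not generative models; their agreement with the
  normal-assumption fits is an empirical report, not a guarantee.
- The Poisson Bayesian sampler is a joint random-walk; for models much
  larger than the univariate arm-effect fits used here, a gradient-based
  sampler would mix better.
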