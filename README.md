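# misslong

Missing-data workflows for small longitudinal immunology cohorts.

Infant immunophenotyping studies accumulate heavy missingness: blood
draws fail, specimens arrive with insufficient volume, visits are
triaged. When 30–40% of flow-cytometry and ELISA assessments are absent,
listwise deletion throws away most of the cohort. `misslong` implements
the complete analysis chain such a study needs, end to end:

1. **Missingness diagnosis** — per-assay missingness maps and Little's
   MCAR test, the chi-square comparison of pattern-wise observed means
   against EM-estimated grand parameters:
   d² = Σ_J n_J (ȳ_J − μ̂_J)ᵀ Σ̂_JJ⁻¹ (ȳ_J − μ̂_J), df = Σ_J p_J − p.
2. **EM for the incomplete multivariate normal** — pattern-grouped
   E-steps via Gaussian conditioning, ML covariance (denominator n),
   monotone observed-data log-likelihood, over-dispersed-start
   ("disperse") agreement checks.
3. **Multiple imputation** — bootstrap-EM (resample rows → EM → draw each
   missing block from its conditional Gaussian), m=5 by default, with
   overimputation coverage diagnostics, and Rubin's-rules pooling:
   T = Ū + (1 + 1/m)B with the Barnard–Rubin style small-m df.
4. **One-step Bayesian models** — MCMC that samples regression
   parameters and the missing responses jointly (data augmentation):
   conjugate Gibbs for the normal likelihood, adaptive random-walk
   Metropolis for a Poisson likelihood on percent-scale counts; R-hat,
   effective sample size, and DIC = D̄ + p_D diagnostics.
5. **Frequentist stage** — Welch two-sample baseline tests with
   Bonferroni adjustment, OLS and quasi-Poisson (log-link) arm-effect
   GLMs, and backward-AIC stepwise logistic selection over imputations.
6. **Concordance reporting** — Pearson regressions between per-variable
   estimate vectors across methods (MI vs Bayesian) and distribution
   assumptions (normal vs Poisson).

Because cohort data of this kind are rarely shareable, the package ships
a **synthetic cohort generator** calibrated to a published two-arm infant
ART study: 24/42 infected infants per arm at visit 1, 12/22 retained at
visit 2, 23 single-visit HIV-exposed-uninfected controls, 17 measurement
columns on bounded assay scales (percentages, MFI, a detection-limited
IL-7 ELISA, log10 viral load), exchangeable latent correlation within the
T-cell panel, and panel-level MCAR/MAR/MNAR missingness injection. The
packaged `paper_fixture()` reproduces the published per-assay
"tests available" counts deterministically.

## Worked example

```python
import misslong as ml

table = ml.paper_fixture()                      # deterministic cohort
sub = table.infected().both_visit_subjects()    # 34 subjects, 68 records

print(ml.missingness_map(table)["panel_rates"])
# {'cd4': 0.0, 'core': 0.0, 'elisa': 0.206, 'flow': 0.309, 'vl': 0.426}

print(ml.little_mcar_test(sub))
# LittleResult(d2=66.9298, df=56, p=0.1505, patterns=7)

imps = ml.emb_impute(sub, m=5, seed=3)          # bootstrap-EM MI
res = ml.MIPooledGLM(imps, "cd4_pct", "normal-identity",
                     ("arm", "visit")).fit()
print(res.summary().loc[["arm"]].round(3))
#        coef     se      t    df      p  ci_low  ci_high    B   Ubar
# arm   4.414  1.868  2.363  65.0  0.021   0.684    8.145  0.0  3.489

ps = ml.fit_bayes(sub, "cd4_pct", ("arm", "visit"), ml.ModelSpec(),
                  ml.McmcConfig(n_iter=10_000, burn_in=4000, seed=1))
print(round(ps["arm"]["mean"], 3), round(ps["arm"]["sd"], 3),
      round(ps["arm"]["rhat"], 4))
# 4.429 1.91 1.0001
```

Reading the numbers: the missingness map shows CD4% complete and ~31% /
~21% of flow / ELISA records missing; Little's test (p = 0.15) finds no
evidence against MCAR, so both imputation frameworks are admissible. The
MI-pooled and Bayesian arm coefficients agree (≈ +4.4 CD4 percentage
points for the early-treatment arm at the follow-up visit, p ≈ 0.02–0.05)
— the early arm shows higher CD4% recovery. Since CD4% itself is never
missing, the between-imputation variance B is 0 and the pooled fit
reduces to the complete-data fit, as it should.

The full tree — simulate → diagnose → impute → pooled GLMs (normal +
Poisson) → Bayesian fits (normal + Poisson) → concordance — runs as

```python
report = ml.run_pipeline()          # packaged fixture, all 15 responses
ml.write_report(report, "report.json")
```

or from the shell:

```bash
misslong simulate --fixture --out cohort.csv
misslong diagnose --in cohort.csv
misslong run-all --in cohort.csv --seed 1 --out report.json
```

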