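"""End-to-end pipeline: simulate → diagnose → impute → pooled GLMs →
Bayesian fits → cross-method/cross-distribution concordance.

The report mirrors the analysis tree of a two-arm longitudinal cohort
study: observed summaries and baseline two-sample tests, a missingness
map with Little's MCAR test, Rubin-pooled multiple-imputation estimates
and one-step Bayesian posterior summaries under both normal and Poisson
response assumptions, and Pearson regressions between the per-variable
estimate vectors of every method/distribution pairing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import BayesGLM, McmcConfig, ModelSpec
from .cohort import (CohortConfig, LongTable, MissingnessSpec, generate_cohort,
                     inject_missingness, paper_fixture)
from .diagnostics import little_mcar_test, missingness_map
from .glm import MIPooledGLM, bonferroni, welch_t
from .impute import emb_impute, overimpute
from .variables import RESPONSE_VARIABLES

TRANSFORMS = ("identity", "natural-log")


@dataclass
class ConcordanceResult:
    """OLS line and Pearson correlation between two estimate vectors."""

    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    n: int
    transform_a: str = "identity"
    transform_b: str = "identity"
    degenerate: bool = False

    def to_dict(self):
        return {k: getattr(self, k) for k in
                ("slope", "intercept", "r", "r2", "p_value", "n",
                 "transform_a", "transform_b", "degenerate")}


def _apply_transform(x, transform):
    x = np.asarray(x, float)
    if transform == "identity":
        return x
    if transform == "natural-log":
        if (x <= 0).any():
            raise ValueError("natural-log transform requires positive values")
        return np.log(x)
    raise ValueError(f"unknown transform {transform!r}")


def estimate_concordance(estimates_a, estimates_b, transform_a="identity",
                         transform_b="identity") -> ConcordanceResult:
    """Pearson linear regression of b on a (slope, R^2, p)."""
    a = _apply_transform(estimates_a, transform_a)
    b = _apply_transform(estimates_b, transform_b)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("estimates must be finite")
    if a.std() == 0 or b.std() == 0:
        return ConcordanceResult(np.nan, np.nan, np.nan, np.nan, np.nan,
                                 int(a.size), transform_a, transform_b,
                                 degenerate=True)
    res = stats.linregress(a, b)
    return ConcordanceResult(float(res.slope), float(res.intercept),
                             float(res.rvalue), float(res.rvalue**2),
                             float(res.pvalue), int(a.size),
                             transform_a, transform_b)


@dataclass
class AnalysisConfig:
    """Knobs of the analysis stages (models, MCMC length, diagnostics)."""

    m: int = 5
    covariates: tuple = ("arm", "visit")
    responses: tuple = tuple(RESPONSE_VARIABLES)
    mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(n_iter=10_000,
                                                                burn_in=4000))
    overimpute_variable: str | None = "cd27_naive_cd4_pct"
    alpha: float = 0.05
    seed: int = 0


@dataclass
class PipelineReport:
    """Machine-readable record of every pipeline stage."""

    meta: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> "ok"/"failed"/"skipped"
    observed_summary: list = field(default_factory=list)
    baseline_tests: list = field(default_factory=list)
    missingness: dict = field(default_factory=dict)
    little: dict = field(default_factory=dict)
    mi_estimates: list = field(default_factory=list)
    bayes_estimates: list = field(default_factory=list)
    concordance: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    schema_version: str = "1"

    @property
    def ok(self) -> bool:
        return not any(v == "failed" for v in self.stages.values())

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "meta": self.meta,
            "stages": self.stages,
            "observed_summary": self.observed_summary,
            "baseline_tests": self.baseline_tests,
            "missingness": self.missingness,
            "little": self.little,
            "mi_estimates": self.mi_estimates,
            "bayes_estimates": self.bayes_estimates,
            "concordance": self.concordance,
            "diagnostics": self.diagnostics,
            "errors": self.errors,
        }

    # -- estimate access -------------------------------------------------
    def estimate_vectors(self, method: str, family: str, column: str = "arm_effect"):
        """Per-variable estimate vector for one method/distribution."""
        src = self.mi_estimates if method == "mi" else self.bayes_estimates
        rows = [r for r in src if r["family"] == family]
        return ([r["response"] for r in rows], np.array([r[column] for r in rows]))

    def markdown(self) -> str:
        lines = ["# Pipeline report", ""]
        lines.append(f"Seed: {self.meta.get('seed')}  |  stages: "
                     + ", ".join(f"{k}={v}" for k, v in self.stages.items()))
        lines.append("")
        if self.baseline_tests:
            lines += ["## Baseline comparisons (HEU vs HIV-infected, visit 1)", "",
                      "| Variable | Mean (HEU) | Mean (HIV) | t | p | Bonferroni |",
                      "|---|---|---|---|---|---|"]
            for r in self.baseline_tests:
                lines.append(
                    f"| {r['variable']} | {r['mean_heu']:.2f} | {r['mean_hiv']:.2f} "
                    f"| {r['t']:.3f} | {r['p']:.4g} | {'*' if r['significant'] else ''} |")
            lines.append("")
        if self.little:
            lines.append("## Little's MCAR test")
            lines.append("")
            for name, r in self.little.items():
                lines.append(f"- {name}: d2={r['d2']:.2f}, df={r['df']}, "
                             f"p={r['p_value']:.4g}"
                             + ("" if r["applicable"] else " (inapplicable)"))
            lines.append("")
        for title, rows in (("## Multiple imputation (Rubin-pooled)", self.mi_estimates),
                            ("## Bayesian one-step models", self.bayes_estimates)):
            if not rows:
                continue
            lines += [title, "", "| Response | Family | Mean (Early) | Estimate | SE | p |",
                      "|---|---|---|---|---|---|"]
            for r in rows:
                lines.append(
                    f"| {r['response']} | {r['family']} | {r['predicted_mean']:.3f} "
                    f"| {r['arm_effect']:.4g} | {r['se']:.4g} | {r['p']:.3g} |")
            lines.append("")
        if self.concordance:
            lines += ["## Concordance (Pearson regression)", ""]
            for name, c in self.concordance.items():
                if c.get("degenerate"):
                    lines.append(f"- {name}: degenerate (zero variance)")
                else:
                    lines.append(f"- {name}: slope={c['slope']:.3f}, "
                                 f"R2={c['r2']:.3f}, p={c['p_value']:.3g}, n={c['n']}")
            lines.append("")
        return "\n".join(lines)


def _observed_summary(table: LongTable) -> list:
    rows = []
    for (g, v), sub in table.df.groupby(["group", "visit"]):
        for s in table.specs:
            col = sub[s.name].dropna()
            if len(col) == 0:
                continue
            rows.append({"group": g, "visit": int(v), "variable": s.name,
                         "mean": float(col.mean()),
                         "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                         "n": int(len(col))})
    return rows


def _baseline_tests(table: LongTable, alpha: float) -> list:
    """Welch tests of HEU vs pooled HIV-infected at visit 1 (observed data)."""
    v1 = table.df[table.df["visit"] == 1]
    heu = v1[v1["group"] == "HEU"]
    hiv = v1[v1["group"] != "HEU"]
    rows = []
    variables = ["age_days"] + [s.name for s in table.specs if s.name != "log10_vl"]
    for name in variables:
        a, b = heu[name].dropna(), hiv[name].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        res = welch_t(a.mean(), max(a.std(ddof=1), 1e-12), len(a),
                      b.mean(), max(b.std(ddof=1), 1e-12), len(b))
        rows.append({"variable": name, "mean_heu": float(a.mean()),
                     "sd_heu": float(a.std(ddof=1)), "n_heu": int(len(a)),
                     "mean_hiv": float(b.mean()), "sd_hiv": float(b.std(ddof=1)),
                     "n_hiv": int(len(b)), "t": res.t, "df": res.df, "p": res.p_value})
    flags = bonferroni([r["p"] for r in rows], alpha=alpha)
    for r, f in zip(rows, flags):
        r["significant"] = bool(f)
    return rows


def run_pipeline(cohort_config: CohortConfig | None = None,
                 missingness_spec: MissingnessSpec | None = None,
                 analysis: AnalysisConfig | None = None,
                 table: LongTable | None = None) -> PipelineReport:
    """Execute the full analysis tree and return a :class:`PipelineReport`.

    With no configs the packaged deterministic fixture cohort is used.
    A stage failure marks that stage ``failed`` and skips its dependents.
    """
    analysis = analysis or AnalysisConfig()
    report = PipelineReport()
    report.meta = {"seed": analysis.seed, "m": analysis.m,
                   "covariates": list(analysis.covariates),
                   "mcmc": {"n_iter": analysis.mcmc.n_iter,
                            "burn_in": analysis.mcmc.burn_in,
                            "n_chains": analysis.mcmc.n_chains}}

    # --- simulate -------------------------------------------------------
    try:
        if table is None:
            if cohort_config is None and missingness_spec is None:
                table = paper_fixture()
            else:
                cohort_config = cohort_config or CohortConfig()
                table = generate_cohort(cohort_config)
                if missingness_spec is not None:
                    table = inject_missingness(table, missingness_spec,
                                               seed=analysis.seed + 1)
        report.meta["cohort"] = {"n_rows": len(table),
                                 "seed": table.meta.get("seed")}
        report.observed_summary = _observed_summary(table)
        report.stages["simulate"] = "ok"
    except Exception as exc:  # pragma: no cover - defensive
        report.stages["simulate"] = "failed"
        report.errors["simulate"] = str(exc)
        for st in ("diagnose", "baseline", "impute", "fit-mi", "fit-bayes", "compare"):
            report.stages[st] = "skipped"
        return report

    # --- diagnose -------------------------------------------------------
    try:
        mm = missingness_map(table)
        report.missingness = {"n_records": mm["n_records"],
                              "variable_rates": mm["variable_rates"],
                              "panel_rates": mm["panel_rates"]}
        longitudinal = table.infected().both_visit_subjects()
        little = {}
        for name, sub in (("visit1", table.infected().subset(
                              table.infected().df["visit"] == 1)),
                          ("stacked", longitudinal)):
            res = little_mcar_test(sub)
            little[name] = {"d2": res.d2, "df": res.df, "p_value": res.p_value,
                            "n_patterns": res.n_patterns,
                            "applicable": res.applicable}
        report.little = little
        report.stages["diagnose"] = "ok"
    except Exception as exc:
        report.stages["diagnose"] = "failed"
        report.errors["diagnose"] = str(exc)

    # --- baseline Welch tests ------------------------------------------
    try:
        report.baseline_tests = _baseline_tests(table, analysis.alpha)
        report.stages["baseline"] = "ok"
    except Exception as exc:
        report.stages["baseline"] = "failed"
        report.errors["baseline"] = str(exc)

    # --- impute ---------------------------------------------------------
    longitudinal = table.infected().both_visit_subjects()
    try:
        imps = emb_impute(longitudinal, m=analysis.m, seed=analysis.seed + 11)
        report.diagnostics["imputation"] = {
            "m": imps.m, "n_imputed_cells": imps.n_imputed_cells,
            "n_clipped": imps.n_clipped}
        if analysis.overimpute_variable:
            ov = overimpute(longitudinal, analysis.overimpute_variable,
                            seed=analysis.seed + 12)
            report.diagnostics["overimputation"] = {
                "variable": ov.variable, "coverage": ov.coverage,
                "n_cells": int(ov.observed.size)}
        report.stages["impute"] = "ok"
    except Exception as exc:
        imps = None
        report.stages["impute"] = "failed"
        report.errors["impute"] = str(exc)

    # --- pooled GLMs over imputations ----------------------------------
    if imps is not None:
        try:
            rows = []
            for response in analysis.responses:
                for family in ("normal-identity", "poisson-log"):
                    res = MIPooledGLM(imps, response, family,
                                      analysis.covariates).fit()
                    pe = res["arm"]
                    lo, hi = pe.ci()
                    rows.append({"response": response, "family": family,
                                 "arm_effect": pe.qbar, "se": pe.se,
                                 "p": pe.p_value, "ci_low": lo, "ci_high": hi,
                                 "B": pe.b, "Ubar": pe.ubar,
                                 "predicted_mean": res.predicted_mean()})
            report.mi_estimates = rows
            report.stages["fit-mi"] = "ok"
        except Exception as exc:
            report.stages["fit-mi"] = "failed"
            report.errors["fit-mi"] = str(exc)
    else:
        report.stages["fit-mi"] = "skipped"

    # --- Bayesian one-step models --------------------------------------
    try:
        rows = []
        rhat_table, dic_table = {}, {}
        for i, response in enumerate(analysis.responses):
            for family in ("normal-identity", "poisson-log"):
                mc = McmcConfig(n_iter=analysis.mcmc.n_iter,
                                burn_in=analysis.mcmc.burn_in,
                                n_chains=analysis.mcmc.n_chains,
                                thin=analysis.mcmc.thin,
                                seed=analysis.seed + 100 + i)
                model = BayesGLM(longitudinal, response, analysis.covariates,
                                 ModelSpec(likelihood=family))
                ps = model.fit(mc)
                arm = ps["arm"]
                pm = float(sum(ps.mean[ps.terms.index(t)]
                               for t in ("intercept", "arm", "visit")
                               if t in ps.terms))
                if family == "poisson-log":
                    pm = float(np.exp(pm))
                rows.append({"response": response, "family": family,
                             "arm_effect": arm["mean"], "se": arm["sd"],
                             "p": arm["p"], "ci_low": arm["ci"][0],
                             "ci_high": arm["ci"][1], "predicted_mean": pm,
                             "rhat": arm["rhat"], "converged": ps.converged})
                rhat_table[f"{response}/{family}"] = float(np.nanmax(ps.rhat))
                dic_table[f"{response}/{family}"] = ps.dic
        report.bayes_estimates = rows
        report.diagnostics["rhat"] = rhat_table
        report.diagnostics["dic"] = dic_table
        report.stages["fit-bayes"] = "ok"
    except Exception as exc:
        report.stages["fit-bayes"] = "failed"
        report.errors["fit-bayes"] = str(exc)

    # --- concordance ----------------------------------------------------
    if len(analysis.responses) < 3:
        report.stages["compare"] = "skipped"
        report.errors.setdefault(
            "compare", "fewer than 3 responses: concordance undefined")
    elif report.stages.get("fit-mi") == "ok" and report.stages.get("fit-bayes") == "ok":
        try:
            conc = {}
            for column in ("arm_effect", "predicted_mean"):
                for fam, tag in (("normal-identity", "normal"),
                                 ("poisson-log", "poisson")):
                    _, a = report.estimate_vectors("mi", fam, column)
                    _, b = report.estimate_vectors("bayes", fam, column)
                    conc[f"mi_vs_bayes/{tag}/{column}"] = \
                        estimate_concordance(a, b).to_dict()
                for meth in ("mi", "bayes"):
                    _, a = report.estimate_vectors(meth, "normal-identity", column)
                    _, b = report.estimate_vectors(meth, "poisson-log", column)
                    conc[f"{meth}_normal_vs_poisson/{column}"] = \
                        estimate_concordance(a, b).to_dict()
                    if column == "predicted_mean" and (a > 0).all():
                        conc[f"{meth}_normal_vs_poisson/{column}/log"] = \
                            estimate_concordance(a, b,
                                                 transform_a="natural-log").to_dict()
            report.concordance = conc
            report.stages["compare"] = "ok"
        except Exception as exc:
            report.stages["compare"] = "failed"
            report.errors["compare"] = str(exc)
    else:
        report.stages["compare"] = "skipped"

    return report


def write_report(report: PipelineReport, path) -> None:
    """Write the report as JSON (machine) and Markdown (human) files."""
    path = str(path)
    json_path = path if path.endswith(".json") else path + ".json"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True,
                  allow_nan=True, default=float)
    md_path = json_path[: -len(".json")] + ".md"
    with open(md_path, "w", encoding="utf-8") as fh:
        fh.write(report.markdown())


def read_table(path, specs=None) -> LongTable:
    """Read a long-format cohort CSV (empty fields = missing)."""
    return LongTable.from_csv(path, specs=specs)
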