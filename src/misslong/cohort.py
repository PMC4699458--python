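"""Synthetic longitudinal cohort generation with controllable missingness.

The generator reproduces the structure the downstream analyses assume:
two treatment arms observed at up to two visits with nested retention, a
single-visit control group, bounded assay scales calibrated to published
per-(group, visit) means and SDs, exchangeable latent correlation within
the T-cell panel, and panel-level missingness under MCAR, MAR or MNAR
mechanisms.  Values are drawn through a Gaussian copula and mapped to each
variable's truncated (or, for detection-limited assays, censored) normal
with moment-matched latent parameters.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .variables import (RESPONSE_VARIABLES, GROUPS, PANELS, VariableSpec,
                        default_variables, sample_bounded)

META_COLUMNS = ["subject_id", "group", "visit", "age_days", "art_day"]

#: default fixture seed
FIXTURE_SEED = 20151215

#: published visit-age targets (days): (group, visit) -> (mean, sd)
DEFAULT_AGES = {
    ("ART-Def", 1): (102.6, 33.9),
    ("ART-Early", 1): (118.4, 36.2),
    ("ART-Def", 2): (263.0, 57.2),
    ("ART-Early", 2): (265.2, 71.5),
    ("HEU", 1): (129.7, 54.7),
}

#: (q25, median, q75) of ART initiation day by arm
DEFAULT_ART_QUANTILES = {"ART-Early": (46.0, 54.0, 61.0), "ART-Def": (171.0, 220.0, 341.0)}

DEFAULT_GROUP_SIZES = {
    ("ART-Def", 1): 24, ("ART-Def", 2): 12,
    ("ART-Early", 1): 42, ("ART-Early", 2): 22,
    ("HEU", 1): 23,
}


@dataclass
class CohortConfig:
    """Cohort geometry and generating parameters."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    ages: dict = field(default_factory=lambda: dict(DEFAULT_AGES))
    art_quantiles: dict = field(default_factory=lambda: dict(DEFAULT_ART_QUANTILES))
    #: additive shift (natural scale) applied to the ART-Early visit-2 mean
    arm_effect: dict = field(default_factory=dict)
    #: exchangeable latent correlation within each corr_group
    rho: float = 0.3
    seed: int = FIXTURE_SEED

    def validate(self):
        for (g, v), n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for ({g}, {v})")
        for g in ("ART-Def", "ART-Early"):
            n1 = self.group_sizes.get((g, 1), 0)
            n2 = self.group_sizes.get((g, 2), 0)
            if n2 > n1:
                raise ValueError(f"visit-2 size exceeds visit-1 size for {g}")
        for g, (q1, q2, q3) in self.art_quantiles.items():
            if not q1 <= q2 <= q3:
                raise ValueError(f"ART quantile targets not ordered for {g}")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")


@dataclass
class MissingnessSpec:
    """Mechanism and per-panel target rates for missingness injection.

    ``mechanism`` is MCAR, MAR or MNAR.  Masking is panel-level by default
    (a failed blood draw drops a whole assay panel for that visit); MNAR is
    necessarily cell-level since each variable's own value drives its
    masking.  The ``cd4`` and ``core`` panels are never masked.
    """

    mechanism: str = "MCAR"
    rates: dict = field(default_factory=lambda: {"flow": 0.31, "elisa": 0.20, "vl": 0.0})
    mar_driver: str = "cd4_pct"
    mar_slope: float = 1.0
    mnar_slope: float = 1.0
    level: str = "panel"

    def validate(self):
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for panel, r in self.rates.items():
            if panel not in PANELS:
                raise ValueError(f"unknown panel {panel!r}")
            if not 0.0 <= r < 1.0:
                raise ValueError(f"rate for {panel} must be in [0, 1), got {r}")
        if self.rates.get("cd4", 0.0) != 0.0 or self.rates.get("core", 0.0) != 0.0:
            raise ValueError("cd4 and core panels are never masked")
        if self.level not in ("panel", "cell"):
            raise ValueError("level must be 'panel' or 'cell'")


class LongTable:
    """Subject-visit rows of measurements with an explicit missingness mask.

    The backing store is a pandas DataFrame with metadata columns
    (subject_id, group, visit, age_days, art_day) followed by one column
    per measurement; a missing cell is NaN and the boolean mask is derived
    from it (mask true ⇔ value absent).
    """

    def __init__(self, df: pd.DataFrame, specs: list[VariableSpec], meta: dict | None = None):
        self.specs = list(specs)
        self.columns = [s.name for s in self.specs]
        missing_cols = [c for c in META_COLUMNS + self.columns if c not in df.columns]
        if missing_cols:
            raise ValueError(f"LongTable missing columns: {missing_cols}")
        self.df = df.reset_index(drop=True)
        self.meta = dict(meta or {})
        keys = list(zip(self.df["subject_id"], self.df["visit"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject_id, visit) keys")

    # -- views -----------------------------------------------------------
    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask over the measurement columns."""
        return self.df[self.columns].isna()

    def values(self, columns=None) -> np.ndarray:
        return self.df[list(columns or self.columns)].to_numpy(float)

    def subset(self, rows) -> "LongTable":
        return LongTable(self.df.loc[rows].copy(), self.specs, self.meta)

    def infected(self) -> "LongTable":
        return self.subset(self.df["group"] != "HEU")

    def both_visit_subjects(self) -> "LongTable":
        v2 = set(self.df.loc[self.df["visit"] == 2, "subject_id"])
        return self.subset(self.df["subject_id"].isin(v2))

    def spec_for(self, name: str) -> VariableSpec:
        return next(s for s in self.specs if s.name == name)

    def copy(self) -> "LongTable":
        return LongTable(self.df.copy(), self.specs, dict(self.meta))

    def __len__(self):
        return len(self.df)

    def content_hash(self) -> str:
        buf = io.StringIO()
        self.df.to_csv(buf, index=False, float_format="%.12g")
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path):
        """RFC-4180 CSV, UTF-8, missing cells as empty fields."""
        self.df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")

    @classmethod
    def from_csv(cls, path, specs=None) -> "LongTable":
        specs = list(specs) if specs is not None else default_variables()
        try:
            df = pd.read_csv(path, encoding="utf-8")
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"empty input file: {path}") from exc
        known = set(META_COLUMNS) | {s.name for s in specs}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValueError(f"unknown columns in {path}: {unknown}")
        absent = [c for c in META_COLUMNS + [s.name for s in specs] if c not in df.columns]
        if absent:
            raise ValueError(f"missing required columns in {path}: {absent}")
        bad = df.loc[~df["group"].isin(GROUPS)]
        if len(bad):
            raise ValueError(f"unknown group label at row {bad.index[0]}")
        for s in specs:
            lo, hi = s.bounds
            col = df[s.name]
            out = col.notna() & ((col < lo) | (col > hi))
            if out.any():
                raise ValueError(
                    f"value outside bounds for {s.name} at row {int(np.argmax(out.to_numpy()))}"
                )
        return cls(df, specs)


def _corr_matrix(specs, rho):
    p = len(specs)
    R = np.eye(p)
    groups = {}
    for i, s in enumerate(specs):
        if s.corr_group:
            groups.setdefault(s.corr_group, []).append(i)
    for idx in groups.values():
        for i in idx:
            for j in idx:
                if i != j:
                    R[i, j] = rho
    return R


def lognormal_from_quantiles(q25, q50, q75):
    """Log-normal (mu, sigma) matched to the printed median and IQR."""
    mu = np.log(q50)
    z75 = stats.norm.ppf(0.75)
    if q75 > q25 > 0:
        sigma = (np.log(q75) - np.log(q25)) / (2 * z75)
    else:
        sigma = 0.0
    return mu, sigma


def generate_cohort(config: CohortConfig, specs: list[VariableSpec] | None = None) -> LongTable:
    """Draw a complete (pre-missingness) cohort matching the calibration targets.

    Subjects seen at visit 2 are a subset of the visit-1 subjects; birth
    weight is drawn once per subject and carried across visits; cells with
    no calibration target (viral load in the uninfected group) are
    structurally absent.
    """
    config.validate()
    specs = list(specs) if specs is not None else default_variables()
    rng = np.random.default_rng(config.seed)
    R = _corr_matrix(specs, config.rho)
    L = np.linalg.cholesky(R)
    rows = []
    sid = 0
    subjects = {}  # group -> list of (subject_id, art_day, birth_weight holder)
    for group in GROUPS:
        n1 = config.group_sizes.get((group, 1), 0)
        ids = [f"{group[:3].upper()}{sid + i:03d}" for i in range(n1)]
        sid += n1
        art = np.full(n1, np.nan)
        if group in config.art_quantiles:
            mu, sg = lognormal_from_quantiles(*config.art_quantiles[group])
            art = np.exp(mu + sg * rng.standard_normal(n1))
        subjects[group] = {"ids": ids, "art": art, "bw": {}}

    for group in GROUPS:
        for visit in (1, 2):
            n = config.group_sizes.get((group, visit), 0)
            if n == 0:
                continue
            ids = subjects[group]["ids"][:n]  # visit-2 subset nested in visit-1
            amean, asd = config.ages[(group, visit)]
            ages = np.clip(amean + asd * rng.standard_normal(n), 1.0, 720.0)
            Z = rng.standard_normal((n, len(specs))) @ L.T
            block = {}
            for j, s in enumerate(specs):
                key = (group, visit)
                if key not in s.moments:
                    block[s.name] = np.full(n, np.nan)
                    continue
                mean, sd = s.moments[key]
                if group == "ART-Early" and visit == 2:
                    mean = mean + config.arm_effect.get(s.name, 0.0)
                lo, hi = s.bounds
                if not lo <= mean <= hi:
                    raise ValueError(
                        f"infeasible spec for variable {s.name!r}: shifted mean "
                        f"{mean} outside bounds {s.bounds}"
                    )
                block[s.name] = sample_bounded(Z[:, j], mean, sd, s.bounds, s.censored)
            for i in range(n):
                subj = ids[i]
                rec = {
                    "subject_id": subj,
                    "group": group,
                    "visit": visit,
                    "age_days": round(float(ages[i]), 1),
                    "art_day": (round(float(subjects[group]["art"][i]), 1)
                                if not np.isnan(subjects[group]["art"][i]) else np.nan),
                }
                for s in specs:
                    v = block[s.name][i]
                    if s.name == "birth_weight_g" and not np.isnan(v):
                        v = subjects[group]["bw"].setdefault(subj, float(v))
                    rec[s.name] = float(v) if not np.isnan(v) else np.nan
                rows.append(rec)

    df = pd.DataFrame(rows, columns=META_COLUMNS + [s.name for s in specs])
    cfg_hash = hashlib.sha256(repr(sorted(config.group_sizes.items())).encode()).hexdigest()[:12]
    return LongTable(df, specs, meta={"seed": config.seed, "config_hash": cfg_hash})


def _calibrate_intercept(driver_std, slope, rate):
    """Intercept making mean(logistic(a + slope*driver)) equal the target rate."""
    if rate <= 0.0:
        return -np.inf

    def marg(a):
        return special.expit(a + slope * driver_std).mean() - rate

    return optimize.brentq(marg, -40.0, 40.0)


def inject_missingness(table: LongTable, spec: MissingnessSpec, seed: int) -> LongTable:
    """Mask cells of ``table`` according to the requested mechanism.

    Observed values are never altered; masking only sets cells to NaN.
    Under MAR the masking probability is ``logistic(a + slope * driver)``
    with the intercept calibrated so the marginal rate hits the target;
    MNAR uses each variable's own (standardized) value as the driver and is
    therefore cell-level.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    out = table.copy()
    df = out.df
    panels = {p: [s.name for s in table.specs if s.panel == p] for p in PANELS}

    if spec.mechanism == "MAR":
        dspec = table.spec_for(spec.mar_driver)
        if spec.rates.get(dspec.panel, 0.0) > 0.0:
            raise ValueError(
                f"MAR driver {spec.mar_driver!r} is itself maskable (panel {dspec.panel})"
            )
        d = df[spec.mar_driver].to_numpy(float)
        if np.isnan(d).any():
            raise ValueError("MAR driver must be fully observed")
        d_std = (d - d.mean()) / d.std()

    if spec.mechanism == "MNAR":
        for panel, rate in spec.rates.items():
            if rate <= 0.0:
                continue
            for name in panels[panel]:
                x = df[name].to_numpy(float)
                obs = ~np.isnan(x)
                xs = np.zeros(len(x))
                xs[obs] = (x[obs] - x[obs].mean()) / max(x[obs].std(), 1e-12)
                a = _calibrate_intercept(xs[obs], spec.mnar_slope, rate)
                pmask = special.expit(a + spec.mnar_slope * xs)
                hit = obs & (rng.random(len(x)) < pmask)
                df.loc[hit, name] = np.nan
        return out

    for panel, rate in spec.rates.items():
        if rate <= 0.0:
            continue
        cols = panels[panel]
        n = len(df)
        if spec.mechanism == "MCAR":
            pmask = np.full(n, rate)
        else:  # MAR
            a = _calibrate_intercept(d_std, spec.mar_slope, rate)
            pmask = special.expit(a + spec.mar_slope * d_std)
        if spec.level == "panel":
            hit = rng.random(n) < pmask
            df.loc[hit, cols] = np.nan
        else:
            for name in cols:
                hit = rng.random(n) < pmask
                df.loc[hit, name] = np.nan
    return out


#: masked record counts per (group, visit, panel) reproducing the published
#: "tests available" counts (observed n per assay in the summary tables).
#: Visit-1 counts for the longitudinal panels are split (both-visit subjects,
#: single-visit subjects) so the both-visit missingness map shows the
#: published ~31% flow / ~20% ELISA rates.
FIXTURE_MASK_COUNTS = {
    ("ART-Def", 1): {"flow": (2, 4), "elisa": (5, 3), "vl": (5, 5)},
    ("ART-Early", 1): {"flow": (5, 7), "elisa": (7, 7), "vl": (10, 10)},
    ("ART-Def", 2): {"flow": 4, "elisa": 1, "vl": 8},
    ("ART-Early", 2): {"flow": 10, "elisa": 1, "vl": 6},
    ("HEU", 1): {"flow": 3, "elisa": 2, "vl": 0},
}


def paper_fixture(seed: int = FIXTURE_SEED) -> LongTable:
    """Deterministic packaged cohort with the published geometry.

    24/42 infected infants per arm at visit 1, 12/22 retained at visit 2,
    23 single-visit HEU controls; CD4% observed everywhere; flow/ELISA/VL
    panels masked completely at random with exact per-(group, visit)
    counts matching the published observed-n table.
    """
    table = generate_cohort(CohortConfig(seed=seed))
    rng = np.random.default_rng(seed + 1)
    df = table.df
    panels = {p: [s.name for s in table.specs if s.panel == p] for p in ("flow", "elisa", "vl")}
    v2_subjects = set(df.loc[df["visit"] == 2, "subject_id"])
    for (group, visit), counts in FIXTURE_MASK_COUNTS.items():
        in_group = (df["group"] == group) & (df["visit"] == visit)
        both = df.index[in_group & df["subject_id"].isin(v2_subjects)].to_numpy()
        single = df.index[in_group & ~df["subject_id"].isin(v2_subjects)].to_numpy()
        for panel, k in counts.items():
            if isinstance(k, tuple):
                k_both, k_single = k
                hit = np.concatenate([
                    rng.choice(both, size=k_both, replace=False),
                    rng.choice(single, size=k_single, replace=False),
                ]) if k_both + k_single else np.empty(0, int)
            else:
                hit = rng.choice(np.concatenate([both, single]), size=k,
                                 replace=False) if k else np.empty(0, int)
            if hit.size:
                df.loc[hit, panels[panel]] = np.nan
    table.meta["fixture"] = True
    return table
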