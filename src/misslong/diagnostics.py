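"""Missingness characterisation: rate maps and Little's MCAR test.

Little's test compares, for each missingness pattern J, the pattern's
observed-variable means against the EM maximum-likelihood estimates of the
grand mean and covariance:

    d^2 = sum_J  n_J (ybar_J - mu_J)' Sigma_JJ^{-1} (ybar_J - mu_J)

referred to a chi-square with  df = sum_J p_J - p  degrees of freedom,
where p_J is the number of observed variables in pattern J.  A small d^2
(non-significant p) is consistent with missingness completely at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .cohort import LongTable
from .em import MvnEM, MvnParams


@dataclass
class PatternTable:
    """Distinct missingness patterns and their case counts."""

    masks: np.ndarray  # (k, p) boolean, True = missing
    counts: np.ndarray  # (k,)
    columns: list

    @property
    def n_patterns(self):
        return len(self.counts)

    @property
    def total(self):
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.masks, columns=self.columns)
        df["n_cases"] = self.counts
        return df


@dataclass
class LittleResult:
    """Chi-square statistic, df and p-value of Little's MCAR test."""

    d2: float
    df: int
    p_value: float
    n_patterns: int
    params: MvnParams
    applicable: bool = True
    small_patterns: list = field(default_factory=list)

    def __repr__(self):
        flag = "" if self.applicable else " (inapplicable: single pattern)"
        return (f"LittleResult(d2={self.d2:.4f}, df={self.df}, "
                f"p={self.p_value:.4g}, patterns={self.n_patterns}){flag}")


def pattern_table(data, columns=None) -> PatternTable:
    data = np.asarray(data, float)
    mask = np.isnan(data)
    keys, counts = np.unique(mask, axis=0, return_counts=True)
    cols = list(columns) if columns is not None else list(range(data.shape[1]))
    return PatternTable(keys, counts, cols)


def missingness_map(table: LongTable, both_visits_only: bool = True) -> dict:
    """Per-variable and per-panel missing rates plus the subject×variable mask.

    By convention the rates are computed over subjects with both visits
    recorded (the infected longitudinal subset); pass
    ``both_visits_only=False`` to use every row.
    """
    sub = table.infected()
    if both_visits_only:
        sub = sub.both_visit_subjects()
    mask = sub.mask
    n = len(sub)
    var_rates = mask.sum(axis=0) / max(n, 1)
    panel_rates = {}
    for panel in sorted({s.panel for s in table.specs}):
        cols = [s.name for s in table.specs if s.panel == panel]
        panel_rates[panel] = float(mask[cols].to_numpy().mean()) if n else 0.0
    matrix = mask.copy()
    matrix.index = pd.MultiIndex.from_frame(sub.df[["subject_id", "visit"]])
    return {
        "n_records": n,
        "variable_rates": var_rates.to_dict(),
        "panel_rates": panel_rates,
        "matrix": matrix,
    }


def little_mcar_test(data, columns=None, tol: float = 1e-6,
                     max_iter: int = 500) -> LittleResult:
    """Little's chi-square test of MCAR on a numeric matrix or LongTable.

    Continuous measurement columns only; rows with zero observed variables
    are excluded.  With a single missingness pattern the test is undefined:
    d2 = 0, df = 0 and p = 1 are returned with ``applicable=False``.
    """
    if isinstance(data, LongTable):
        columns = columns or data.columns
        data = data.values(columns)
    X = np.asarray(data, float)
    keep = ~np.isnan(X).all(axis=1)
    X = X[keep]
    n, p = X.shape
    model = MvnEM(X)
    params = model.fit(tol=tol, max_iter=max_iter)
    d2 = 0.0
    sum_pj = 0
    small = []
    pats = model.pattern_groups
    for miss, idx in pats:
        obs = np.nonzero(~miss)[0]
        if obs.size == 0:
            continue
        nj = len(idx)
        if nj < 5:
            small.append((miss.copy(), nj))
        ybar = X[np.ix_(idx, obs)].mean(axis=0)
        diff = ybar - params.mean[obs]
        Soo = params.cov[np.ix_(obs, obs)]
        try:
            sol = linalg.solve(Soo, diff, assume_a="pos")
        except linalg.LinAlgError:
            sol = np.linalg.pinv(Soo) @ diff
        d2 += nj * float(diff @ sol)
        sum_pj += obs.size
    df = sum_pj - p
    if len(pats) < 2 or df <= 0:
        return LittleResult(0.0, max(df, 0), 1.0, len(pats), params,
                            applicable=False, small_patterns=small)
    if small:
        warnings.warn(
            f"{len(small)} missingness pattern(s) with fewer than 5 cases; "
            "the chi-square reference may be inaccurate"
        )
    pval = float(stats.chi2.sf(d2, df))
    return LittleResult(float(d2), int(df), pval, len(pats), params,
                        small_patterns=small)
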