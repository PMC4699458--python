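"""Shared fixtures: the deterministic packaged cohort and small toy tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

import misslong as ml
from misslong.cohort import META_COLUMNS
from misslong.variables import VariableSpec


@pytest.fixture(scope="session")
def fixture_table():
    return ml.paper_fixture()


@pytest.fixture(scope="session")
def longitudinal(fixture_table):
    return fixture_table.infected().both_visit_subjects()


@pytest.fixture(scope="session")
def fixture_imputations(longitudinal):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ml.emb_impute(longitudinal, m=5, seed=3)


@pytest.fixture(scope="session")
def fixture_report():
    """One full pipeline run on the packaged cohort (all 15 responses)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ml.run_pipeline(analysis=ml.AnalysisConfig(seed=0))


def make_table(values: np.ndarray, names=None, groups=None, visits=None,
               bounds=(-1e6, 1e6), panel="flow") -> ml.LongTable:
    """Wrap a numeric matrix (NaN = missing) in a minimal LongTable."""
    values = np.asarray(values, float)
    n, p = values.shape
    names = names or [f"v{j}" for j in range(p)]
    specs = [VariableSpec(nm, "positive", panel, bounds=bounds,
                          moments={("ART-Def", 1): (0.0, 1.0)})
             for nm in names]
    # VariableSpec requires mean within bounds; rebuild with safe moments
    specs = [VariableSpec(nm, "positive", panel, bounds=bounds,
                          moments={("ART-Def", 1): (float(np.mean(bounds))
                                                    if np.isfinite(bounds).all()
                                                    else 0.0, 1.0)})
             for nm in names]
    df = pd.DataFrame(values, columns=names)
    df["subject_id"] = [f"S{i:04d}" for i in range(n)]
    df["group"] = groups if groups is not None else "ART-Def"
    df["visit"] = visits if visits is not None else 1
    df["age_days"] = 100.0
    df["art_day"] = np.nan
    return ml.LongTable(df[META_COLUMNS + names], specs)


@pytest.fixture
def make_longtable():
    return make_table


def mvn_sample(rng, n, mean, cov):
    L = np.linalg.cholesky(np.asarray(cov, float))
    return np.asarray(mean, float) + rng.standard_normal((n, len(mean))) @ L.T
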