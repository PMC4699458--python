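"""Cohort generator: calibration, retention, missingness mechanisms, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import misslong as ml
from misslong.cohort import DEFAULT_GROUP_SIZES
from misslong.variables import default_variables


def big_config(n=2000, seed=5):
    return ml.CohortConfig(group_sizes={("ART-Def", 1): n, ("ART-Early", 1): n,
                                        ("ART-Def", 2): n // 2,
                                        ("ART-Early", 2): n // 2,
                                        ("HEU", 1): n // 2}, seed=seed)


class TestGenerateCohort:
    def test_deterministic_under_fixed_seed(self):
        cfg = ml.CohortConfig(seed=42)
        a, b = ml.generate_cohort(cfg), ml.generate_cohort(cfg)
        assert a.content_hash() == b.content_hash()

    def test_visit2_subjects_nested_in_visit1(self):
        t = ml.generate_cohort(ml.CohortConfig(seed=3))
        v1 = set(t.df.loc[t.df["visit"] == 1, "subject_id"])
        v2 = set(t.df.loc[t.df["visit"] == 2, "subject_id"])
        assert v2 <= v1

    def test_small_sample_mean_within_three_standard_errors(self):
        """24 deferred-arm CD4% draws: mean within 32.9 ± 3·7.9/sqrt(24)."""
        t = ml.generate_cohort(ml.CohortConfig(seed=9))
        sub = t.df[(t.df["group"] == "ART-Def") & (t.df["visit"] == 1)]
        assert len(sub) == 24
        assert abs(sub["cd4_pct"].mean() - 32.9) < 3 * 7.9 / np.sqrt(24)

    def test_large_sample_calibration_two_percent(self):
        """n=2000 per cell: mean and (feasible) SD within 2% of targets."""
        t = ml.generate_cohort(big_config())
        sub = t.df[(t.df["group"] == "ART-Def") & (t.df["visit"] == 1)]
        # variables whose printed SD is attainable under truncation
        for name, (m, sd) in [("cd4_pct", (32.9, 7.9)),
                              ("cd27_naive_cd8_pct", (53.7, 18.1)),
                              ("cd38_mfi", (1402.0, 790.9))]:
            assert sub[name].mean() == pytest.approx(m, rel=0.02), name
            assert sub[name].std() == pytest.approx(sd, rel=0.02), name

    def test_all_values_within_bounds(self):
        t = ml.generate_cohort(big_config(seed=6))
        for s in t.specs:
            col = t.df[s.name].dropna()
            assert (col >= s.bounds[0]).all() and (col <= s.bounds[1]).all()

    def test_birth_weight_constant_within_subject(self):
        t = ml.generate_cohort(ml.CohortConfig(seed=2))
        per = t.df.groupby("subject_id")["birth_weight_g"].nunique()
        assert (per <= 1).all() or (per == 1).all()

    def test_art_initiation_quantiles_roughly_matched(self):
        t = ml.generate_cohort(big_config(seed=8))
        early = t.df[(t.df["group"] == "ART-Early") & (t.df["visit"] == 1)]["art_day"]
        assert np.median(early) == pytest.approx(54.0, rel=0.1)
        q1, q3 = np.percentile(early, [25, 75])
        assert q1 == pytest.approx(46.0, rel=0.15)
        assert q3 == pytest.approx(61.0, rel=0.15)

    def test_degenerate_sd_gives_constant_values(self):
        specs = [v for v in default_variables() if v.name == "cd4_pct"]
        tiny = ml.VariableSpec("cd4_pct", "percent", "cd4", bounds=(0, 100),
                               corr_group=None,
                               moments={k: (50.0, 1e-9) for k in specs[0].moments})
        t = ml.generate_cohort(ml.CohortConfig(seed=1), [tiny])
        assert np.allclose(t.df["cd4_pct"], 50.0, atol=1e-6)

    def test_infeasible_mean_raises_naming_variable(self):
        bad = ml.VariableSpec("cd4_pct", "percent", "cd4", bounds=(0, 100),
                              moments={("ART-Def", 1): (90.0, 5.0)})
        cfg = ml.CohortConfig(arm_effect={"cd4_pct": 20.0})
        # the visit-2 overlay pushes the ART-Early mean past the upper bound
        bad2 = ml.VariableSpec("cd4_pct", "percent", "cd4", bounds=(0, 100),
                               moments={("ART-Def", 1): (90.0, 5.0),
                                        ("ART-Early", 1): (90.0, 5.0),
                                        ("ART-Def", 2): (90.0, 5.0),
                                        ("ART-Early", 2): (90.0, 5.0)})
        with pytest.raises(ValueError, match="cd4_pct"):
            ml.generate_cohort(cfg, [bad2])

    @given(n1=st.integers(2, 10), n2=st.integers(0, 10))
    @settings(max_examples=10, deadline=None)
    def test_retention_nesting_property(self, n1, n2):
        n2 = min(n2, n1)
        cfg = ml.CohortConfig(group_sizes={("ART-Def", 1): n1, ("ART-Def", 2): n2,
                                           ("ART-Early", 1): 2, ("HEU", 1): 0},
                              seed=0)
        t = ml.generate_cohort(cfg)
        v2 = t.df[t.df["visit"] == 2]
        v1_ids = set(t.df.loc[t.df["visit"] == 1, "subject_id"])
        assert set(v2["subject_id"]) <= v1_ids
        assert t.mask.equals(t.df[t.columns].isna())


class TestInjectMissingness:
    def test_mcar_rate_within_binomial_band(self):
        t = ml.generate_cohort(big_config(seed=4))
        spec = ml.MissingnessSpec(rates={"flow": 0.31})
        out = ml.inject_missingness(t, spec, seed=1)
        n = len(out)
        frac = out.mask["cd95_pct_cd8"].mean()
        assert abs(frac - 0.31) < 3 * np.sqrt(0.31 * 0.69 / n)

    def test_rate_zero_leaves_table_unchanged(self):
        t = ml.generate_cohort(ml.CohortConfig(seed=1))
        out = ml.inject_missingness(t, ml.MissingnessSpec(rates={"flow": 0.0}), seed=2)
        assert out.content_hash() == t.content_hash()

    def test_observed_values_unchanged_by_masking(self):
        t = ml.generate_cohort(ml.CohortConfig(seed=1))
        out = ml.inject_missingness(t, ml.MissingnessSpec(rates={"flow": 0.4}), seed=2)
        still = ~out.mask["cd95_pct_cd8"]
        assert np.allclose(out.df.loc[still, "cd95_pct_cd8"],
                           t.df.loc[still, "cd95_pct_cd8"])

    def test_mnar_masked_values_exceed_observed_mean(self):
        """Positive self-slope selects high values into missingness."""
        t = ml.generate_cohort(big_config(seed=7))
        spec = ml.MissingnessSpec(mechanism="MNAR", rates={"flow": 0.3},
                                  mnar_slope=2.0)
        out = ml.inject_missingness(t, spec, seed=3)
        masked = out.mask["cd27_naive_cd8_pct"] & ~t.mask["cd27_naive_cd8_pct"]
        assert t.df.loc[masked, "cd27_naive_cd8_pct"].mean() > \
            t.df.loc[~masked, "cd27_naive_cd8_pct"].mean()

    def test_mcar_contract_masked_vs_observed_means_similar(self):
        t = ml.generate_cohort(big_config(n=2500, seed=12))
        out = ml.inject_missingness(t, ml.MissingnessSpec(rates={"flow": 0.3}),
                                    seed=4)
        x = t.df["cd95_pct_cd8"].to_numpy()
        m = out.mask["cd95_pct_cd8"].to_numpy()
        se = np.sqrt(x[m].var() / m.sum() + x[~m].var() / (~m).sum())
        assert abs(x[m].mean() - x[~m].mean()) < 3 * se

    def test_mar_driver_must_not_be_maskable(self):
        t = ml.generate_cohort(ml.CohortConfig(seed=1))
        spec = ml.MissingnessSpec(mechanism="MAR", rates={"flow": 0.3},
                                  mar_driver="cd95_pct_cd8")
        with pytest.raises(ValueError, match="maskable"):
            ml.inject_missingness(t, spec, seed=1)

    def test_mar_marginal_rate_calibrated(self):
        t = ml.generate_cohort(big_config(seed=13))
        spec = ml.MissingnessSpec(mechanism="MAR", rates={"flow": 0.25},
                                  mar_driver="cd4_pct", mar_slope=1.5)
        out = ml.inject_missingness(t, spec, seed=5)
        frac = out.mask["cd95_pct_cd8"].mean()
        assert frac == pytest.approx(0.25, abs=0.02)


class TestPaperFixture:
    def test_published_cohort_geometry(self, fixture_table):
        df = fixture_table.df
        infected = df[df["group"] != "HEU"]
        assert (infected["visit"] == 1).sum() == 66
        assert (infected["visit"] == 2).sum() == 34
        assert (df["group"] == "HEU").sum() == 23
        sizes = infected.groupby(["group", "visit"]).size().to_dict()
        assert sizes == {("ART-Def", 1): 24, ("ART-Def", 2): 12,
                         ("ART-Early", 1): 42, ("ART-Early", 2): 22}

    def test_cd4_panel_never_missing(self, fixture_table):
        assert fixture_table.mask["cd4_pct"].sum() == 0
        assert fixture_table.mask["birth_weight_g"].sum() == 0

    def test_longitudinal_panel_rates_match_published_map(self, fixture_table):
        mm = ml.missingness_map(fixture_table)
        assert mm["n_records"] == 68
        assert mm["panel_rates"]["cd4"] == 0.0
        assert mm["panel_rates"]["elisa"] == pytest.approx(14 / 68)
        assert mm["panel_rates"]["flow"] == pytest.approx(21 / 68)

    def test_fixture_is_deterministic(self, fixture_table):
        assert fixture_table.content_hash() == ml.paper_fixture().content_hash()


class TestCsvRoundTrip:
    def test_round_trip_preserves_values_and_mask(self, tmp_path, fixture_table):
        path = tmp_path / "cohort.csv"
        fixture_table.to_csv(path)
        back = ml.read_table(path)
        assert back.mask.equals(fixture_table.mask)
        a = fixture_table.values()
        b = back.values()
        assert np.allclose(a[~np.isnan(a)], b[~np.isnan(b)])

    def test_unknown_column_rejected(self, tmp_path, fixture_table):
        path = tmp_path / "bad.csv"
        df = fixture_table.df.copy()
        df["mystery"] = 1.0
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="mystery"):
            ml.read_table(path)

    def test_out_of_bounds_value_rejected(self, tmp_path, fixture_table):
        path = tmp_path / "bad.csv"
        df = fixture_table.df.copy()
        df.loc[0, "cd4_pct"] = 150.0
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="cd4_pct"):
            ml.read_table(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            ml.read_table(path)
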