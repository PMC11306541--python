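"""Normalization, DP/MAD filtering and QC behavior."""

import numpy as np
import pandas as pd
import pytest

from phoskin import preprocess
from phoskin.maxquant_io import PY
from phoskin.synthetic_data import simulate_cohort
from .conftest import make_site_matrix, small_config


class TestMedianSiteNormalization:
    def test_scale_factors_from_per_sample_medians(self):
        # per-sample medians {10, 20, 40} -> target 20 -> factors {2, 1, 0.5}
        m = make_site_matrix(
            {
                "P1|1|M1": {"A": 5.0, "B": 10.0, "C": 20.0},
                "P2|2|M1": {"A": 10.0, "B": 20.0, "C": 40.0},
                "P3|3|M1": {"A": 20.0, "B": 40.0, "C": 80.0},
            }
        )
        out = preprocess.normalize_median_site(m)
        np.testing.assert_allclose(out.data["A"], [10.0, 20.0, 40.0])
        np.testing.assert_allclose(out.data["B"], [10.0, 20.0, 40.0])
        np.testing.assert_allclose(out.data["C"], [10.0, 20.0, 40.0])

    def test_already_normalized_is_identity(self):
        m = make_site_matrix(
            {"P1|1|M1": {"A": 10.0, "B": 10.0}, "P2|2|M1": {"A": 30.0, "B": 30.0}}
        )
        out = preprocess.normalize_median_site(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_single_sample_unchanged(self):
        m = make_site_matrix({"P1|1|M1": {"A": 7.0}, "P2|2|M1": {"A": 9.0}})
        pd.testing.assert_frame_equal(preprocess.normalize_median_site(m).data, m.data)

    def test_equal_medians_after_normalization(self, cohort):
        out = preprocess.normalize_median_site(cohort["sites_global"])
        med = out.data.median(axis=0, skipna=True)
        assert np.allclose(med, med.iloc[0], rtol=1e-9)

    def test_missing_preserved_and_empty_sample_rejected(self):
        m = make_site_matrix(
            {"P1|1|M1": {"A": 10.0, "B": np.nan}, "P2|2|M1": {"A": 30.0, "B": np.nan}}
        )
        with pytest.raises(ValueError, match="B"):
            preprocess.normalize_median_site(m)


class TestTotalCountNormalization:
    def test_scaling_by_mean_over_total(self):
        m = make_site_matrix(
            {"P1|1|M1": {"A": 10.0, "B": 10.0}}, channel=PY
        )
        out = preprocess.normalize_total_count(m, pd.Series({"A": 100, "B": 200}))
        np.testing.assert_allclose(out.data.loc["P1|1|M1"], [15.0, 7.5])

    def test_equal_totals_identity(self):
        m = make_site_matrix({"P1|1|M1": {"A": 10.0, "B": 12.0}}, channel=PY)
        out = preprocess.normalize_total_count(m, pd.Series({"A": 50, "B": 50}))
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_missing_total_rejected(self):
        m = make_site_matrix({"P1|1|M1": {"A": 10.0, "B": 12.0}}, channel=PY)
        with pytest.raises(ValueError, match="B"):
            preprocess.normalize_total_count(m, pd.Series({"A": 50}))


class TestDataPresence:
    def test_boundary_at_ten_percent_of_42(self):
        cols = [f"S{i:02d}" for i in range(42)]
        row4 = {c: (1.0 if i < 4 else np.nan) for i, c in enumerate(cols)}
        row5 = {c: (1.0 if i < 5 else np.nan) for i, c in enumerate(cols)}
        m = pd.DataFrame({"f4": row4, "f5": row5}).T
        out = preprocess.filter_data_presence(m, 0.10)
        assert list(out.index) == ["f5"]  # 4/42 = 9.5% dropped; 5/42 = 11.9% kept

    def test_full_presence_keeps_only_complete(self):
        m = pd.DataFrame(
            {"A": [1.0, 1.0], "B": [2.0, np.nan]}, index=["full", "holey"]
        )
        out = preprocess.filter_data_presence(m, 1.0)
        assert list(out.index) == ["full"]

    def test_nested_in_threshold(self, cohort):
        m = cohort["sites_global"].data
        loose = set(preprocess.filter_data_presence(m, 0.10).index)
        strict = set(preprocess.filter_data_presence(m, 0.50).index)
        assert strict <= loose


class TestMadSelection:
    def test_known_mad_value(self):
        vals = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 100.0]], index=["f"])
        assert preprocess.mad_per_feature(vals)["f"] == 1.0

    def test_constant_feature_ranked_last(self):
        m = pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [1.0, 9.0], "s3": [1.0, 1.0]},
            index=["const", "vary"],
        )
        out = preprocess.select_most_variable_mad(m, 0.5)
        assert list(out.index) == ["vary"]

    def test_ceiling_count(self):
        m = pd.DataFrame(
            np.random.default_rng(0).normal(size=(20, 5)),
            index=[f"f{i:02d}" for i in range(20)],
        )
        assert len(preprocess.select_most_variable_mad(m, 0.1)) == 2

    def test_invariant_to_sample_order_and_shared_shift(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(30, 8)),
                         index=[f"f{i:02d}" for i in range(30)],
                         columns=[f"s{i}" for i in range(8)])
        sel = preprocess.select_most_variable_mad(m, 0.2).index
        shuffled = m[list(m.columns[::-1])]
        assert list(preprocess.select_most_variable_mad(shuffled, 0.2).index) == list(sel)
        assert list(preprocess.select_most_variable_mad(m + 7.0, 0.2).index) == list(sel)


class TestLog2Prepare:
    def test_values_and_missing(self):
        m = pd.DataFrame({"A": [8.0, np.nan]}, index=["f1", "f2"])
        out = preprocess.log2_prepare(m)
        assert out.loc["f1", "A"] == 3.0
        assert np.isnan(out.loc["f2", "A"])

    def test_order_preserved(self):
        m = pd.DataFrame({"A": [2.0, 16.0, 4.0]}, index=list("abc"))
        out = preprocess.log2_prepare(m)
        assert out["A"].rank().tolist() == m["A"].rank().tolist()


class TestQcCorrelations:
    def test_perfect_rank_agreement(self):
        m = make_site_matrix(
            {
                "P1|1|M1": {"A": 1.0, "B": 1.0, "C": 1.0},
                "P2|2|M1": {"A": np.nan, "B": 1.0, "C": 1.0},
                "P3|3|M1": {"A": np.nan, "B": np.nan, "C": 1.0},
            }
        )
        clin = pd.DataFrame({"cellularity_pct": [10.0, 40.0, 70.0]}, index=["A", "B", "C"])
        rep = preprocess.qc_correlations(m, clin)
        assert rep["cellularity_spearman"]["rho"] == pytest.approx(1.0)
        clin_rev = pd.DataFrame({"cellularity_pct": [70.0, 40.0, 10.0]},
                                index=["A", "B", "C"])
        assert preprocess.qc_correlations(m, clin_rev)["cellularity_spearman"][
            "rho"] == pytest.approx(-1.0)

    def test_cellularity_association_emerges_in_cohort(self):
        """With intensity coupled to cellularity, higher-purity samples keep
        more identifications, so counts and cellularity correlate."""
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            cfg = small_config(seed=500 + seed, cellularity_effect=1.5)
            _, sg, _, _, clin = simulate_cohort(cfg)
            rep = preprocess.qc_correlations(sg, clin)
            sp = rep["cellularity_spearman"]
            hits += (sp["rho"] > 0) and (sp["p"] < 0.05)
        assert hits / n_rep >= 0.8
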