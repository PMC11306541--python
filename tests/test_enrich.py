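"""Enrichment scoring against an independent running-sum oracle."""

import numpy as np
import pandas as pd
import pytest

from phoskin.enrich import (
    EnrichmentResult,
    SignatureSet,
    average_by_cluster,
    dedup_by_window,
    preranked_score,
    ptm_sea_score,
    ssgsea_matrix,
    ssgsea_score,
)
from phoskin.synthetic_data import simulate_cohort
from .conftest import make_site_matrix, small_config


def oracle_es(values: dict, members, alpha: float) -> float:
    """Brute-force running-sum reference: walk the ranked list accumulating
    the weighted in-set and uniform out-of-set ECDF difference."""
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    in_flags = [k in members for k, _ in items]
    n_in = sum(in_flags)
    w_tot = sum(abs(v) ** alpha for (k, v), f in zip(items, in_flags) if f)
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for (k, v), f in zip(items, in_flags):
        if f:
            p_in += (abs(v) ** alpha) / w_tot
        else:
            p_out += 1.0 / (n - n_in)
        es += p_in - p_out
    return es


class TestSsgseaScore:
    def test_five_key_worked_example(self):
        values = pd.Series({"k1": 5.0, "k2": 4.0, "k3": 3.0, "k4": 2.0, "k5": 1.0})
        sig = SignatureSet("top2", frozenset({"k1", "k2"}), min_size=1)
        es = ssgsea_score(values, sig, alpha=1.0)
        # ranked walk: P_in = 5/9, 1, 1, 1, 1; P_out = 0, 0, 1/3, 2/3, 1
        assert es == pytest.approx(23.0 / 9.0, abs=1e-12)
        assert es == pytest.approx(oracle_es(values.to_dict(), {"k1", "k2"}, 1.0),
                                   abs=1e-12)

    def test_matches_oracle_on_random_profiles(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            keys = [f"g{i:02d}" for i in range(50)]
            values = pd.Series(rng.normal(0, 2, 50), index=keys)
            members = set(rng.choice(keys, size=rng.integers(3, 20), replace=False))
            sig = SignatureSet(f"s{rep}", frozenset(members), min_size=1)
            for alpha in (0.0, 0.25, 1.0):
                assert ssgsea_score(values, sig, alpha=alpha) == pytest.approx(
                    oracle_es(values.to_dict(), members, alpha), abs=1e-12
                )

    def test_sign_follows_rank_position(self):
        values = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"k{i}" for i in range(10)])
        top = SignatureSet("top", frozenset({"k0", "k1"}), min_size=1)
        bottom = SignatureSet("bottom", frozenset({"k8", "k9"}), min_size=1)
        assert ssgsea_score(values, top) > 0
        assert ssgsea_score(values, bottom) < 0

    def test_full_coverage_scores_zero(self):
        values = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0})
        sig = SignatureSet("all", frozenset("abc"), min_size=1)
        assert ssgsea_score(values, sig) == 0.0

    def test_alpha_zero_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        values = pd.Series(rng.normal(size=30), index=[f"k{i:02d}" for i in range(30)])
        sig = SignatureSet("s", frozenset({"k01", "k05", "k20", "k11"}), min_size=1)
        a = ssgsea_score(values, sig, alpha=0.0)
        b = ssgsea_score(np.exp(values), sig, alpha=0.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_alpha_zero_reversal_negates(self):
        values = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        sig = SignatureSet("s", frozenset({"a"}), min_size=1)
        fwd = ssgsea_score(values, sig, alpha=0.0)
        rev = ssgsea_score(-values, sig, alpha=0.0)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_all_tied_values_score_zero(self):
        values = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        sig = SignatureSet("s", frozenset({"a"}), min_size=1)
        assert ssgsea_score(values, sig) == 0.0


class TestSizeBounds:
    def test_undersized_signature_skipped(self):
        m = pd.DataFrame({"s1": np.arange(10.0)}, index=[f"k{i}" for i in range(10)])
        small = SignatureSet("small", frozenset({"k1", "k2"}))  # min_size 5 default
        res = ssgsea_matrix(m, [small])
        assert "small" in res.skipped
        assert res.es.empty or "small" not in res.es.index


class TestPtmSea:
    def test_duplicate_window_keeps_most_abundant(self):
        m = make_site_matrix(
            {
                "P1|10|M1": {"A": 60.0, "B": 40.0},   # row sum 100
                "P2|20|M1": {"A": 30.0, "B": 20.0},   # same window, row sum 50
                "P3|30|M1": {"A": 10.0, "B": 10.0},
            },
            windows=["AAAAAAASAAAAAAA", "AAAAAAASAAAAAAA", "CCCCCCCSCCCCCCC"],
        )
        dd = dedup_by_window(m)
        assert dd.loc["AAAAAAASAAAAAAA", "A"] == 60.0
        assert len(dd) == 2

    def test_dedup_identity_without_duplicates(self):
        m = make_site_matrix(
            {"P1|10|M1": {"A": 60.0}, "P2|20|M1": {"A": 30.0}},
            windows=["AAAAAAASAAAAAAA", "CCCCCCCSCCCCCCC"],
        )
        dd = dedup_by_window(m)
        assert sorted(dd["A"]) == [30.0, 60.0]

    def test_malformed_window_rejected(self):
        m = make_site_matrix({"P1|10|M1": {"A": 1.0}}, windows=["SHORT"])
        with pytest.raises(ValueError, match="15"):
            dedup_by_window(m)

    def test_planted_signature_elevates_member_samples(self):
        """Sites of a kinase-driven signature are up-shifted in the kinase's
        subtype; those samples' enrichment scores should exceed the rest."""
        hits = 0
        n_rep = 15
        for seed in range(n_rep):
            cfg = small_config(seed=700 + seed)
            truth, sg, *_ = simulate_cohort(cfg)
            k = "KIN03"
            sub = truth.kinase_subtype[k]
            driven = [s for s, drivers in truth.site_drivers.items()
                      if k in drivers and s in sg.meta.index]
            wins = frozenset(sg.meta.loc[driven, "window"])
            sig = SignatureSet(f"{k}_substrates", wins, min_size=3)
            res = ptm_sea_score(sg, [sig])
            if res.es.empty:
                continue
            es = res.es.iloc[0]
            in_sub = truth.subtype_labels == sub
            hits += es[in_sub].mean() > es[~in_sub].mean()
        assert hits / n_rep >= 0.95


class TestClusterAveraging:
    def test_arithmetic_mean_and_singletons(self):
        es = pd.DataFrame({"s1": [1.0], "s2": [3.0], "s3": [7.0]}, index=["sig"])
        res = EnrichmentResult(es=es)
        labels = pd.Series({"s1": "c1", "s2": "c1", "s3": "c2"})
        means = average_by_cluster(res, labels)
        assert means.loc["sig", "c1"] == pytest.approx(2.0)
        assert means.loc["sig", "c2"] == pytest.approx(7.0)

    def test_permuting_within_cluster_invariant(self):
        es = pd.DataFrame({"s1": [1.0], "s2": [3.0], "s3": [7.0]}, index=["sig"])
        labels = pd.Series({"s1": "c1", "s2": "c1", "s3": "c2"})
        m1 = average_by_cluster(EnrichmentResult(es=es), labels)
        m2 = average_by_cluster(EnrichmentResult(es=es[["s2", "s1", "s3"]]), labels)
        pd.testing.assert_frame_equal(m1, m2)

    def test_unlabeled_sample_rejected(self):
        es = pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["sig"])
        with pytest.raises(ValueError, match="unlabeled"):
            average_by_cluster(EnrichmentResult(es=es), pd.Series({"s1": "c1"}))


class TestPreranked:
    def test_uses_alpha_one_weights(self):
        metric = pd.Series({"k1": 5.0, "k2": 4.0, "k3": 3.0, "k4": 2.0, "k5": 1.0})
        sig = SignatureSet("top2", frozenset({"k1", "k2"}), min_size=1)
        res = preranked_score(metric, [sig])
        assert res.es.loc["top2", "preranked"] == pytest.approx(23.0 / 9.0, abs=1e-12)
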