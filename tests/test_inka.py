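"""INKA evidence arms and scoring: worked examples, brute-force oracle,
algebraic invariants, group pooling."""

import numpy as np
import pandas as pd
import pytest

from phoskin.inka import (
    EvidenceArms,
    build_evidence_arms,
    compare_profiles,
    group_profile,
    inka_score,
    sample_profiles,
    score_matrix,
    site_evidence,
    top_n,
)
from phoskin.maxquant_io import KinaseSubstrateNetwork, PeptideEvidence
from phoskin.synthetic_data import SimulationConfig, simulate_cohort, simulate_network
from .conftest import make_site_matrix, small_config


def tiny_setup():
    """One kinase K1 with two self sites (counts 3, 5), one activation-loop
    site (2), two curated substrate sites (1, 1) and one predicted substrate
    (score 3.0, count 4)."""
    sites = make_site_matrix(
        {
            "K1|100|M1": {"A": 1.0},
            "K1|150|M1": {"A": 1.0},
            "K1|200|M1": {"A": 1.0},
            "P1|10|M1": {"A": 1.0},
            "P2|20|M1": {"A": 1.0},
            "P3|30|M1": {"A": 1.0},
        }
    )
    counts = pd.DataFrame(
        {"A": [3, 5, 2, 1, 1, 4]},
        index=[f"_pep{i}_" for i in range(6)],
    )
    pep_meta = pd.DataFrame(
        {
            "protein": ["K1", "K1", "K1", "P1", "P2", "P3"],
            "position": [100, 150, 200, 10, 20, 30],
        },
        index=counts.index,
    )
    ev = PeptideEvidence(counts=counts, peptide_meta=pep_meta)
    net = KinaseSubstrateNetwork(
        edges=pd.DataFrame(
            [
                {"kinase": "K1", "substrate": "P1", "position": 10, "residue": "S",
                 "source": "curated", "score": np.nan},
                {"kinase": "K1", "substrate": "P2", "position": 20, "residue": "S",
                 "source": "curated", "score": np.nan},
                {"kinase": "K1", "substrate": "P3", "position": 30, "residue": "S",
                 "source": "predicted", "score": 3.0},
            ]
        ),
        self_sites={"K1": {("K1", 100), ("K1", 150)}},
        activation_loop_sites={"K1": {("K1", 200)}},
    )
    return sites, ev, net


class TestEvidenceArms:
    def test_worked_example(self):
        sites, ev, net = tiny_setup()
        arms = build_evidence_arms(sites, ev, net, "A")
        row = arms.arms.loc["K1"]
        assert tuple(row[["C_kin", "C_act", "C_psp", "C_nwk"]]) == (8, 2, 2, 4)

    def test_prediction_score_cutoff_boundary(self):
        sites, ev, net = tiny_setup()
        net.edges.loc[2, "score"] = 1.9
        arms = build_evidence_arms(sites, ev, net, "A", nwk_min_score=2.0)
        assert arms.arms.loc["K1", "C_nwk"] == 0
        net.edges.loc[2, "score"] = 2.0
        arms = build_evidence_arms(sites, ev, net, "A", nwk_min_score=2.0)
        assert arms.arms.loc["K1", "C_nwk"] == 4

    def test_dual_sourced_site_counted_once_as_curated(self):
        sites, ev, net = tiny_setup()
        extra = pd.DataFrame([{"kinase": "K1", "substrate": "P1", "position": 10,
                               "residue": "S", "source": "predicted", "score": 5.0}])
        net = KinaseSubstrateNetwork(
            edges=pd.concat([net.edges, extra], ignore_index=True),
            self_sites=net.self_sites,
            activation_loop_sites=net.activation_loop_sites,
        )
        arms = build_evidence_arms(sites, ev, net, "A")
        assert arms.arms.loc["K1", "C_psp"] == 2
        assert arms.arms.loc["K1", "C_nwk"] == 4  # P1 not double counted

    def test_negative_arm_rejected(self):
        with pytest.raises(ValueError):
            EvidenceArms("u", pd.DataFrame(
                [[-1, 0, 0, 0]], columns=["C_kin", "C_act", "C_psp", "C_nwk"],
                index=["K1"]))


class TestInkaScore:
    def test_geometric_mean(self):
        arms = EvidenceArms("u", pd.DataFrame(
            [[10, 6, 3, 1]], columns=["C_kin", "C_act", "C_psp", "C_nwk"],
            index=["K1"]))
        prof = inka_score(arms)
        assert prof.table.loc["K1", "K"] == 16
        assert prof.table.loc["K1", "S"] == 4
        assert prof.table.loc["K1", "score"] == pytest.approx(8.0)

    def test_kinase_centric_only_excluded_from_ranking(self):
        arms = EvidenceArms("u", pd.DataFrame(
            [[10, 6, 0, 0], [1, 0, 4, 0]],
            columns=["C_kin", "C_act", "C_psp", "C_nwk"], index=["K1", "K2"]))
        prof = inka_score(arms)
        assert list(prof.table.index) == ["K2"]
        assert list(prof.kinase_centric_only.index) == ["K1"]

    def test_tie_broken_alphabetically(self):
        arms = EvidenceArms("u", pd.DataFrame(
            [[8, 0, 8, 0], [8, 0, 8, 0], [1, 0, 1, 0]],
            columns=["C_kin", "C_act", "C_psp", "C_nwk"], index=["B", "A", "C"]))
        prof = inka_score(arms)
        assert list(prof.table.index) == ["A", "B", "C"]
        assert list(prof.table["rank"]) == [1, 2, 3]

    def test_scale_equivariance(self):
        sites, ev, net = tiny_setup()
        base = inka_score(build_evidence_arms(sites, ev, net, "A"))
        scaled_counts = ev.counts * 3
        ev3 = PeptideEvidence(counts=scaled_counts, peptide_meta=ev.peptide_meta)
        scaled = inka_score(build_evidence_arms(sites, ev3, net, "A"))
        assert scaled.table.loc["K1", "score"] == pytest.approx(
            3 * base.table.loc["K1", "score"])

    def test_monotone_in_added_evidence(self):
        sites, ev, net = tiny_setup()
        base = inka_score(build_evidence_arms(sites, ev, net, "A"))
        for pep in ev.counts.index:
            boosted = ev.counts.copy()
            boosted.loc[pep] += 5
            prof = inka_score(build_evidence_arms(
                sites, PeptideEvidence(counts=boosted, peptide_meta=ev.peptide_meta),
                net, "A"))
            assert prof.table.loc["K1", "score"] >= base.table.loc["K1", "score"]


def brute_force_arms(sites, ev, net, sample, nwk_min_score=2.0):
    """Independent re-derivation: iterate every network relation and sum the
    per-site counts read directly off the evidence table."""
    per_site = {}
    for pep in ev.counts.index:
        key = (ev.peptide_meta.loc[pep, "protein"], int(ev.peptide_meta.loc[pep, "position"]))
        if key in set(zip(sites.meta["protein"], sites.meta["position"])):
            per_site[key] = per_site.get(key, 0) + int(ev.counts.loc[pep, sample])
    out = {}
    for k in net.kinases:
        act = set(net.activation_loop_sites.get(k, set()))
        own = set(net.self_sites.get(k, set())) - act
        cur, pred = set(), set()
        for r in net.edges.itertuples():
            if r.kinase != k:
                continue
            if r.source == "curated":
                cur.add((r.substrate, int(r.position)))
            elif r.source == "predicted" and r.score >= nwk_min_score:
                pred.add((r.substrate, int(r.position)))
        pred -= cur
        get = lambda ss: sum(per_site.get(s, 0) for s in ss)
        out[k] = (get(own), get(act), get(cur), get(pred))
    return out


class TestBruteForceOracle:
    def test_random_small_networks_exact(self, cohort=None):
        rng = np.random.default_rng(3)
        for rep in range(5):
            cfg = SimulationConfig(
                n_samples=6, n_kinases=3, n_sites_global=18, n_sites_py=8,
                edges_per_kinase=3, seed=int(rng.integers(1e6)),
            )
            truth, sg, sy, ev, clin = simulate_cohort(cfg)
            for sample in sg.samples[:3]:
                arms = build_evidence_arms(sg, ev, truth.network, sample)
                brute = brute_force_arms(sg, ev, truth.network, sample)
                for k, expect in brute.items():
                    got = tuple(arms.arms.loc[k])
                    assert got == expect, (k, got, expect)
                prof = inka_score(arms)
                for k in prof.table.index:
                    K = brute[k][0] + brute[k][1]
                    S = brute[k][2] + brute[k][3]
                    assert prof.table.loc[k, "score"] == pytest.approx(np.sqrt(K * S))


class TestGroupProfiles:
    def test_single_sample_group_equals_sample_profile(self):
        cfg = small_config(seed=21)
        truth, sg, sy, ev, clin = simulate_cohort(cfg)
        labels = pd.Series("g0", index=sg.samples)
        labels.iloc[0] = "solo"
        gprofs = group_profile(sg, ev, truth.network, labels)
        solo = gprofs["solo"].table
        single = inka_score(build_evidence_arms(sg, ev, truth.network, sg.samples[0])).table
        pd.testing.assert_series_equal(solo["score"], single["score"], check_names=False)

    def test_duplicated_evidence_doubles_score(self):
        sites, ev, net = tiny_setup()
        sites2 = make_site_matrix(
            {k: {"A": v["A"], "B": v["A"]} for k, v in
             sites.data.T.to_dict().items()}
        )
        counts2 = pd.concat([ev.counts, ev.counts.rename(columns={"A": "B"})], axis=1)
        ev2 = PeptideEvidence(counts=counts2, peptide_meta=ev.peptide_meta)
        labels = pd.Series({"A": "g", "B": "g"})
        gprofs = group_profile(sites2, ev2, net, labels)
        single = inka_score(build_evidence_arms(sites2, ev2, net, "A"))
        assert gprofs["g"].table.loc["K1", "score"] == pytest.approx(
            2 * single.table.loc["K1", "score"])
        assert gprofs["g"].table.loc["K1", "dp_pct"] == 100.0

    def test_dp_percentage_arithmetic(self):
        # a kinase scoring in 14 of 42 samples is annotated DP 33.3%
        assert round(100 * 14 / 42, 1) == 33.3


class TestTopN:
    def test_returns_all_when_fewer_scored(self):
        arms = EvidenceArms("u", pd.DataFrame(
            [[4, 0, 4, 0], [2, 0, 2, 0]],
            columns=["C_kin", "C_act", "C_psp", "C_nwk"], index=["A", "B"]))
        prof = inka_score(arms)
        assert len(top_n(prof, 20)) == 2


class TestCompareProfiles:
    def test_identical_groups_p_one(self):
        smat = pd.DataFrame(
            {"a1": [5.0], "a2": [7.0], "b1": [5.0], "b2": [7.0]}, index=["K1"]
        )
        labels = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        rep = compare_profiles(smat, labels)
        assert rep.loc["K1", "p"] == pytest.approx(1.0)

    def test_all_zero_kinase_skipped(self):
        smat = pd.DataFrame(
            {"a1": [0.0, 1.0], "a2": [0.0, 2.0], "b1": [0.0, 5.0], "b2": [0.0, 6.0]},
            index=["Kzero", "Kup"],
        )
        labels = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        rep = compare_profiles(smat, labels)
        assert "Kzero" not in rep.index
        assert "Kup" in rep.index

    def test_planted_kinase_detected_across_replicates(self):
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = small_config(seed=800 + seed)
            truth, sg, sy, ev, clin = simulate_cohort(cfg)
            k = cfg.hyper_kinase
            sub = truth.kinase_subtype[k]
            labels = (truth.subtype_labels == sub).map({True: "in", False: "out"})
            smat = score_matrix(sample_profiles(sg, ev, truth.network))
            rep = compare_profiles(smat, labels)
            ok = (k in rep.index and rep.loc[k, "q"] < 0.05
                  and rep.loc[k, "higher_in"] == "in")
            hits += ok
        assert hits / n_rep >= 0.9
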