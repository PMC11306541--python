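"""End-to-end orchestration: simulate -> ingest -> preprocess -> subtype ->
differential -> enrichment -> INKA -> survival, from a single config.

Every stage draws its randomness from a per-stage seed derived from the
global seed and a fixed stage index, so adding a stage never perturbs the
randomness of earlier ones. The machine-readable report contains subtype
labels, significant-feature counts, per-group top-20 INKA tables, survival
associations, file checksums and all seeds/parameters for exact reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffstat, enrich, inka, preprocess, subtype, survival
from .cohort import mutation_frequencies
from .maxquant_io import (
    GLOBAL_PST,
    PY,
    read_clinical,
    read_network,
    read_sites,
    exclude_records,
    filter_class1,
    spectral_counts_from_evidence,
)
from .synthetic_data import SimulationConfig, simulate_cohort, write_fixture

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Counter-based per-stage seed derivation (stable under stage addition)."""
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """All knobs of the full analysis; thresholds mirror the standard
    workflow (class-I 0.75, DP 0.10, MAD top 0.10, BH q 0.05, fold change 2,
    signature sizes 5-1000, top-20 kinases) and are config, not code."""

    workdir: str = "phoskin_run"
    seed: int = 0
    simulate: dict = field(default_factory=dict)   # SimulationConfig overrides
    fixture_dir: str | None = None                 # use existing fixture instead
    class1_threshold: float = 0.75
    dp_fraction: float = 0.10
    mad_top_fraction: float = 0.10
    k_min: int = 2
    k_max: int = 5
    n_resamples: int = 100
    subsample_fraction: float = 0.8
    choose_k: int | None = None
    q_max: float = 0.05
    fc_min: float = 2.0
    nwk_min_score: float = 2.0
    top_n: int = 20
    ssgsea_alpha: float = 0.25
    os_cutoff: float | None = None                 # override the bimodal cutoff
    naive_only: bool = True
    extreme_n: int = 3
    mutation_contrasts: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _kinase_site_signatures(net, sites_meta: pd.DataFrame, min_size: int = 5):
    """Site signatures keyed by flanking window: one set per kinase from its
    substrate-site windows (curated + predicted)."""
    win_by_site = {
        (p, q): w
        for p, q, w in zip(sites_meta["protein"], sites_meta["position"], sites_meta["window"])
    }
    sigs = []
    for k in net.kinases:
        ek = net.edges[net.edges["kinase"] == k]
        wins = {
            win_by_site[(r.substrate, int(r.position))]
            for r in ek.itertuples()
            if (r.substrate, int(r.position)) in win_by_site
        }
        if len(wins) >= min_size:
            sigs.append(enrich.SignatureSet(name=f"{k}_substrates", members=frozenset(wins)))
    return sigs


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to
    ``<workdir>/report.json``). A stage failure raises with the stage name;
    outputs of completed stages stay on disk."""
    work = Path(cfg.workdir)
    work.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(cfg), "stages": {}}
    stage = "setup"
    try:
        # ---- stage 0: cohort -------------------------------------------------
        stage = "simulate"
        if cfg.fixture_dir is None:
            sim_cfg = SimulationConfig(**{"seed": stage_seed(cfg.seed, 0), **cfg.simulate})
            truth, sg, sy, ev, clin = simulate_cohort(sim_cfg)
            fdir = work / "fixture"
            paths = write_fixture(truth, sg, sy, ev, clin, fdir)
        else:
            fdir = Path(cfg.fixture_dir)
            paths = {
                "sites_global": fdir / "Phospho (STY)Sites_global.txt",
                "sites_py": fdir / "Phospho (STY)Sites_pY.txt",
                "evidence": fdir / "evidence.txt",
                "network": fdir / "kinase_substrate_network.tsv",
                "clinical": fdir / "clinical.csv",
            }
        report["stages"]["simulate"] = {
            "checksums": {k: _sha256(v) for k, v in sorted(paths.items())
                          if Path(v).exists()}
        }

        stage = "ingest"
        sites_g = read_sites(paths["sites_global"], GLOBAL_PST)
        sites_y = read_sites(paths["sites_py"], PY)
        evidence = spectral_counts_from_evidence(paths["evidence"])
        net = read_network(paths["network"])
        clinical = read_clinical(paths["clinical"])
        report["stages"]["ingest"] = {
            "n_sites_global": len(sites_g.data),
            "n_sites_py": len(sites_y.data),
            "n_samples_global": len(sites_g.samples),
            "n_samples_py": len(sites_y.samples),
            "mutation_frequencies": mutation_frequencies(clinical),
        }

        # ---- stage 1: preprocess --------------------------------------------
        stage = "preprocess"
        sites_g, rep_g = exclude_records(sites_g, return_report=True)
        sites_y, rep_y = exclude_records(sites_y, return_report=True)
        sites_g = filter_class1(sites_g, cfg.class1_threshold)
        sites_y = filter_class1(sites_y, cfg.class1_threshold)
        norm_g = preprocess.normalize_median_site(sites_g)
        norm_y = preprocess.normalize_total_count(
            sites_y, clinical["lysate_spectral_count"]
        )
        log_g = preprocess.log2_prepare(
            preprocess.filter_data_presence(norm_g, cfg.dp_fraction)
        )
        mad_g = preprocess.select_most_variable_mad(log_g, cfg.mad_top_fraction)
        qc = preprocess.qc_correlations(norm_g, clinical)
        report["stages"]["preprocess"] = {
            "excluded_global": rep_g,
            "excluded_py": rep_y,
            "n_class1_global": len(sites_g.data),
            "n_after_dp": len(log_g.data),
            "n_mad_selected": len(mad_g.data),
            "cellularity_spearman": qc.get("cellularity_spearman"),
        }

        # ---- stage 2: subtype -----------------------------------------------
        stage = "subtype"
        cons = subtype.consensus_cluster(
            mad_g.data,
            k_range=range(cfg.k_min, cfg.k_max + 1),
            n_resamples=cfg.n_resamples,
            subsample_fraction=cfg.subsample_fraction,
            seed=stage_seed(cfg.seed, 2),
            choose_k=cfg.choose_k,
        )
        labels = cons.labels
        labels.to_frame("cluster").to_csv(work / "subtype_labels.csv")
        report["stages"]["subtype"] = {
            "chosen_k": cons.chosen_k,
            "cdf_areas": {str(k): round(v, 6) for k, v in cons.cdf_areas.items()},
            "delta_areas": {str(k): round(v, 6) for k, v in cons.delta_areas.items()},
            "cluster_sizes": labels.value_counts().sort_index().to_dict(),
            "labels": labels.astype(int).to_dict(),
        }

        # ---- stage 3: differential ------------------------------------------
        stage = "differential"
        diff = diffstat.moderated_test(log_g.data, labels)
        sig = diffstat.significant_features(diff, q_max=cfg.q_max, fc_min=cfg.fc_min)
        diff.table.to_csv(work / "differential_sites.tsv", sep="\t")
        diff_out = {
            "n_tested": int(diff.table["tested"].sum()),
            "n_significant": len(sig),
            "d0": round(diff.d0, 4) if np.isfinite(diff.d0) else "inf",
            "s02": round(diff.s02, 6),
        }
        if cfg.mutation_contrasts:
            for gene, col in (("tp53", "tp53_status"), ("kras", "kras_status")):
                glab = clinical[col].reindex(log_g.data.columns)
                if glab.value_counts().min() >= 2 and glab.nunique() == 2:
                    d2 = diffstat.moderated_test(log_g.data, glab)
                    s2 = diffstat.significant_features(
                        d2, q_max=cfg.q_max, fc_min=cfg.fc_min, use_q=False
                    )
                    diff_out[f"{gene}_contrast"] = {
                        "groups": glab.value_counts().to_dict(),
                        "n_significant": len(s2),
                    }
        report["stages"]["differential"] = diff_out

        # ---- stage 4: enrichment --------------------------------------------
        stage = "enrichment"
        sigs = _kinase_site_signatures(net, norm_g.meta)
        enr_out: dict = {"n_site_signatures": len(sigs)}
        if sigs:
            es = enrich.ptm_sea_score(norm_g, sigs, alpha=cfg.ssgsea_alpha)
            means = enrich.average_by_cluster(es, labels)
            es.es.to_csv(work / "ptm_sea_scores.tsv", sep="\t")
            enr_out["cluster_means"] = {
                s: {str(c): round(v, 4) for c, v in row.items()}
                for s, row in means.iterrows()
            }
        report["stages"]["enrichment"] = enr_out

        # ---- stage 5: INKA ---------------------------------------------------
        stage = "inka"
        inka_out = {}
        score_mats = {}
        for channel, sites_c in (("pST", norm_g), ("pY", norm_y)):
            profs = inka.sample_profiles(sites_c, evidence, net,
                                         nwk_min_score=cfg.nwk_min_score,
                                         channel=channel)
            smat = inka.score_matrix(profs)
            score_mats[channel] = smat
            gprofs = inka.group_profile(sites_c, evidence, net,
                                        labels.reindex(sites_c.samples).dropna(),
                                        nwk_min_score=cfg.nwk_min_score,
                                        channel=channel)
            smat.to_csv(work / f"inka_scores_{channel}.tsv", sep="\t")
            inka_out[channel] = {
                str(g): {
                    "top": [
                        {"kinase": k, "score": round(float(r["score"]), 3),
                         "rank": int(r["rank"]), "dp_pct": float(r["dp_pct"])}
                        for k, r in inka.top_n(p, cfg.top_n).iterrows()
                    ]
                }
                for g, p in gprofs.items()
            }
        report["stages"]["inka"] = inka_out

        # ---- stage 6: survival ----------------------------------------------
        stage = "survival"
        smat = score_mats["pST"]
        assoc = survival.spearman_survival(smat, clinical, naive_only=cfg.naive_only)
        assoc.table.to_csv(work / "survival_association.tsv", sep="\t")
        cutoff = cfg.os_cutoff
        if cutoff is None:
            cutoff = survival.bimodal_cutoff(clinical["os_months"])
        surv_out: dict = {
            "n_kinases_assessed": int(len(assoc.table)),
            "cutoff_months": round(cutoff, 2) if cutoff is not None else None,
            "km_by_subtype": {},
        }
        sig_assoc = assoc.table.dropna(subset=["p"])
        surv_out["significant_kinases"] = {
            k: {"rho": round(r["rho"], 3), "p": round(r["p"], 4),
                "direction": r["direction"]}
            for k, r in sig_assoc[sig_assoc["p"] < 0.05].iterrows()
        }
        for g in sorted(labels.unique()):
            ids = labels.index[labels == g]
            km = survival.km_estimate(clinical.loc[ids, "os_months"],
                                      clinical.loc[ids, "event_flag"])
            surv_out["km_by_subtype"][str(g)] = {
                "n": int(len(ids)),
                "median": round(km["median"], 1) if np.isfinite(km["median"]) else None,
            }
        if cutoff is not None:
            try:
                groups = survival.define_outcome_groups(clinical, cutoff,
                                                        naive_only=cfg.naive_only)
                surv_out["outcome_groups"] = {
                    "short": len(groups.short_ids), "long": len(groups.long_ids)
                }
                os_ = clinical["os_months"]
                ext_short = sorted(groups.short_ids, key=lambda s: os_[s])[: cfg.extreme_n]
                ext_long = sorted(groups.long_ids, key=lambda s: -os_[s])[: cfg.extreme_n]
                if len(ext_short) >= 2 and len(ext_long) >= 2:
                    eg = survival.OutcomeGroups(cutoff, ext_short, ext_long,
                                                groups.treatment_naive_only)
                    _, ext_sig = survival.extreme_group_diff(
                        log_g.data, eg, p_max=0.05, fc_min=cfg.fc_min
                    )
                    surv_out["extreme_contrast"] = {
                        "n_short": len(ext_short), "n_long": len(ext_long),
                        "n_significant": len(ext_sig),
                    }
            except ValueError as exc:
                surv_out["outcome_groups"] = {"note": str(exc)}
        report["stages"]["survival"] = surv_out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    out = work / "report.json"
    with open(out, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    log.info("pipeline complete; report at %s", out)
    return report
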