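"""Synthetic PDAC-like phosphoproteomic cohorts with planted ground truth.

The generator emulates the structure of a two-channel label-free tumor
phosphoproteomics study: a global pS/T (IMAC) site matrix and a smaller pY
(immunoprecipitation) matrix, spectral counts derived from an evidence-style
table, class-I localization probabilities, subtype-structured kinase
activities that drive substrate-site intensities through a kinase–substrate
network, intensity-dependent (missing-not-at-random) dropout, and a clinical
table with overall survival tied to a designated prognostic kinase.

Every downstream stage of the pipeline is testable against the planted truth
without any external download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .maxquant_io import (
    GLOBAL_PST,
    PY,
    KinaseSubstrateNetwork,
    PeptideEvidence,
    SiteMatrix,
    site_key,
    write_network,
    write_sites,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: spectral-count model: Poisson mean = SC_SCALE * 2^(SC_EXPONENT * (log2I - base)),
#: capped at cfg.spectral_cap. The sub-unity exponent reflects the saturation of
#: MS/MS sampling at high abundance in shotgun data.
SC_SCALE = 5.0
SC_EXPONENT = 0.6

#: baseline median overall survival (months) at average prognostic activity
OS_BASELINE_MEDIAN = 18.0

#: KRAS allele-variant probabilities among mutant tumors (typed variants plus
#: a fraction with no allele call), matching reported PDAC cohort frequencies
KRAS_VARIANT_PROBS = {
    "G12V": 0.40,
    "G12D": 0.35,
    "G12R": 0.10,
    "G12R/G12V": 0.025,
    "G13D": 0.025,
    "Q61H": 0.025,
    "NA": 0.075,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror a 42-tumor two-channel PDAC cohort: three phospho-subtypes,
    KRAS/TP53 mutation frequencies of 95.2% / 73.8%, 9 of 42 samples without a
    pY channel, and exponential survival with log-hazard proportional to the
    standardized activity of the prognostic kinase.
    """

    n_samples: int = 42
    n_subtypes: int = 3
    n_kinases: int = 18
    n_sites_global: int = 600
    n_sites_py: int = 150
    edges_per_kinase: int = 8
    predicted_fraction: float = 0.35
    activity_base: float = 23.0     # log2 intensity of an average site
    activity_shift: float = 3.0     # log2 shift of a kinase in its assigned subtype
    hyper_kinase: str = "KIN01"     # the designated hyperactive kinase
    hyper_extra_shift: float = 4.0  # extra log2 shift of hyper_kinase in its subtype
    noise_sd: float = 1.0
    missing_gamma0: float = -16.0   # logistic observation model: p = sigmoid(g0 + g1 * log2 I)
    missing_gamma1: float = 0.75
    class1_fraction: float = 0.9
    cellularity_effect: float = 1.0  # log2 offset per unit (cellularity - 50)/50
    prognostic_kinase: str = "KIN02"
    hazard_beta: float = 0.8
    censor_rate: float = 0.25
    naive_fraction: float = 23 / 42
    mut_freq_kras: float = 0.952
    mut_freq_tp53: float = 0.738
    tp53_effect: float = 0.0        # optional log2 shift of tp53_n_sites in TP53-mutant tumors
    tp53_n_sites: int = 30
    py_channel_dropout: float = 9 / 42
    spectral_cap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("predicted_fraction", "class1_fraction", "censor_rate",
                     "naive_fraction", "mut_freq_kras", "mut_freq_tp53",
                     "py_channel_dropout"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_subtypes < 2:
            raise ConfigurationError("n_subtypes must be >= 2")
        for name in ("n_samples", "n_kinases", "n_sites_global", "n_sites_py",
                     "edges_per_kinase", "spectral_cap"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated cohort."""

    subtype_labels: pd.Series              # sample -> 1..n_subtypes
    activities: pd.DataFrame               # kinase x sample, log2 scale (a_{k,s})
    network: KinaseSubstrateNetwork
    survival_months: pd.Series
    event_flag: pd.Series
    treatment_naive: pd.Series
    kinase_subtype: dict[str, int]         # kinase -> assigned subtype
    site_drivers: dict[str, list[str]]     # site key -> parent kinases
    differential_sites: list[str] = field(default_factory=list)
    tp53_sites: list[str] = field(default_factory=list)
    spectral_counts: pd.DataFrame | None = None   # site key x sample
    true_log2: dict = field(default_factory=dict)  # channel -> site x sample log2 intensity
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.subtype_labels.isna().any():
            raise ValueError("every sample needs a subtype label")
        if (self.survival_months <= 0).any():
            raise ValueError("survival_months must be > 0")
        if not np.isfinite(self.activities.values).all():
            raise ValueError("activities must be finite")


def _random_window(rng, residue: str) -> str:
    w = rng.choice(AMINO_ACIDS, size=15)
    w[7] = residue
    return "".join(w)


def _build_channel(kinases, residues_pool, n_sites, edges_per_kinase,
                   predicted_fraction, rng, prefix):
    """Site pool + kinase annotation for one channel.

    Each kinase owns one self site and one activation-loop site on its own
    protein; the remaining sites are substrate-protein sites targeted by
    kinase edges."""
    if edges_per_kinase > n_sites:
        raise ConfigurationError("edges_per_kinase exceeds the channel site pool")
    n_owner = 2 * len(kinases)
    if n_sites <= n_owner:
        raise ConfigurationError("n_sites too small for kinase self/activation-loop sites")
    meta_rows, self_sites, act_sites = [], {}, {}
    for i, k in enumerate(kinases):
        res = rng.choice(residues_pool)
        self_sites[k] = {(k, 100)}
        act_sites[k] = {(k, 200)}
        for pos in (100, 200):
            meta_rows.append((k, k, pos, res, _random_window(rng, res), [k]))
    n_sub = n_sites - n_owner
    sub_meta = []
    for j in range(n_sub):
        prot = f"{prefix}{j + 1:04d}"
        res = rng.choice(residues_pool)
        pos = int(rng.integers(1, 900))
        sub_meta.append((prot, prot, pos, res, _random_window(rng, res), []))
    # substrate sets are disjoint across kinases where the pool allows it, so
    # each substrate site reflects a single kinase's activity
    edge_rows = []
    pool = list(rng.permutation(n_sub))
    for k in kinases:
        take = min(edges_per_kinase, n_sub)
        if len(pool) >= take:
            idx, pool = pool[:take], pool[take:]
        else:
            idx = rng.choice(n_sub, size=take, replace=False)
        for j in idx:
            prot, _gene, pos, res, _w, parents = sub_meta[j]
            parents.append(k)
            predicted = rng.random() < predicted_fraction
            edge_rows.append(
                {
                    "kinase": k,
                    "substrate": prot,
                    "position": pos,
                    "residue": res,
                    "source": "predicted" if predicted else "curated",
                    "score": float(np.round(rng.uniform(1.0, 5.0), 3)) if predicted else np.nan,
                }
            )
    meta_rows.extend(sub_meta)
    meta = pd.DataFrame(
        meta_rows, columns=["protein", "gene", "position", "residue", "window", "parents"]
    )
    edges = pd.DataFrame(edge_rows)
    return meta, edges, self_sites, act_sites


def simulate_network(
    n_kinases: int,
    n_sites: int,
    edges_per_kinase: int,
    predicted_fraction: float = 0.35,
    seed: int = 0,
) -> KinaseSubstrateNetwork:
    """Simulate a kinase–substrate relation set.

    Produces ``n_kinases * edges_per_kinase`` substrate edges (curated or
    predicted, predicted edges scored), plus one self site and one flagged
    activation-loop site per kinase.
    """
    if edges_per_kinase > n_sites:
        raise ConfigurationError("edges_per_kinase cannot exceed n_sites")
    rng = np.random.default_rng(seed)
    kinases = [f"KIN{i + 1:02d}" for i in range(n_kinases)]
    _meta, edges, self_sites, act_sites = _build_channel(
        kinases, np.array(["S", "T", "Y"]), n_sites + 2 * n_kinases,
        edges_per_kinase, predicted_fraction, rng, "SUB",
    )
    return KinaseSubstrateNetwork(edges=edges, self_sites=self_sites,
                                  activation_loop_sites=act_sites)


def _simulate_channel_matrix(meta, activities, cfg, rng, channel, samples,
                             cellularity, tp53_mut, tp53_sites_set):
    """Log-intensity, observation and count model for one channel's sites."""
    n_sites, n_samples = len(meta), len(samples)
    keys = [site_key(p, q, 1) for p, q in zip(meta["protein"], meta["position"])]
    cell_off = cfg.cellularity_effect * (cellularity - 50.0) / 50.0

    logint = np.empty((n_sites, n_samples))
    baseline = rng.normal(cfg.activity_base, 1.5, size=n_sites)
    for i, parents in enumerate(meta["parents"]):
        if parents:
            logint[i] = activities.loc[parents].sum(axis=0).values
        else:
            logint[i] = baseline[i]
    logint += rng.normal(0.0, cfg.noise_sd, size=logint.shape)
    logint += cell_off[None, :]
    if cfg.tp53_effect:
        for i, key in enumerate(keys):
            if key in tp53_sites_set:
                logint[i, tp53_mut.values.astype(bool)] += cfg.tp53_effect

    p_obs = 1.0 / (1.0 + np.exp(-(cfg.missing_gamma0 + cfg.missing_gamma1 * logint)))
    observed = rng.random(logint.shape) < p_obs

    sc_mean = np.minimum(
        cfg.spectral_cap, SC_SCALE * 2.0 ** (SC_EXPONENT * (logint - cfg.activity_base))
    )
    counts = rng.poisson(sc_mean)
    counts[~observed] = 0

    intens = np.where(observed, 2.0 ** logint, np.nan)
    data = pd.DataFrame(intens, index=keys, columns=samples)
    counts_df = pd.DataFrame(counts, index=keys, columns=samples)

    is_class1 = rng.random(n_sites) < cfg.class1_fraction
    loc_prob = np.where(
        is_class1, rng.uniform(0.75, 1.0, n_sites), rng.uniform(0.2, 0.75, n_sites)
    ).round(3)
    meta_df = pd.DataFrame(
        {
            "protein": meta["protein"].values,
            "gene": meta["gene"].values,
            "position": meta["position"].values,
            "residue": meta["residue"].values,
            "window": meta["window"].values,
            "localization_probability": loc_prob,
            "multiplicity": 1,
            "reverse": False,
            "contaminant": False,
        },
        index=keys,
    )
    return SiteMatrix(data, meta_df, channel), counts_df, logint


def simulate_cohort(cfg: SimulationConfig):
    """Simulate a full cohort.

    Returns ``(truth, sites_global, sites_py, evidence, clinical)``:
    the planted :class:`SyntheticTruth`, the pS/T and pY site matrices,
    peptide-level spectral-count evidence, and the clinical table.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_net, r_act, r_glob, r_py, r_clin, r_misc = rngs

    samples = [f"T{i + 1:02d}" for i in range(cfg.n_samples)]
    kinases = [f"KIN{i + 1:02d}" for i in range(cfg.n_kinases)]
    n_st = int(np.ceil(cfg.n_kinases * 2 / 3))
    st_kinases, y_kinases = kinases[:n_st], kinases[n_st:]

    # subtype labels: balanced assignment, then shuffled
    labels = np.tile(np.arange(1, cfg.n_subtypes + 1),
                     int(np.ceil(cfg.n_samples / cfg.n_subtypes)))[: cfg.n_samples]
    r_act.shuffle(labels)
    subtype = pd.Series(labels, index=samples, name="subtype")
    kin_subtype = {k: (i % cfg.n_subtypes) + 1 for i, k in enumerate(kinases)}

    # kinase activities a_{k,s}
    act = np.full((cfg.n_kinases, cfg.n_samples), cfg.activity_base, dtype=float)
    for i, k in enumerate(kinases):
        in_sub = (subtype.values == kin_subtype[k]).astype(float)
        act[i] += cfg.activity_shift * in_sub
        if k == cfg.hyper_kinase:
            act[i] += cfg.hyper_extra_shift * in_sub
    act += r_act.normal(0.0, 1.0, size=act.shape)
    activities = pd.DataFrame(act, index=kinases, columns=samples)

    # clinical covariates drawn before intensities (cellularity feeds the signal)
    cellularity = np.round(r_clin.uniform(20, 80, cfg.n_samples), 1)
    kras_mut = r_clin.random(cfg.n_samples) < cfg.mut_freq_kras
    variants = list(KRAS_VARIANT_PROBS)
    probs = np.array(list(KRAS_VARIANT_PROBS.values()))
    alleles = np.where(
        kras_mut, r_clin.choice(variants, size=cfg.n_samples, p=probs / probs.sum()), "WT"
    )
    tp53_mut = pd.Series(r_clin.random(cfg.n_samples) < cfg.mut_freq_tp53,
                         index=samples).astype(int)
    naive = (r_clin.random(cfg.n_samples) < cfg.naive_fraction).astype(int)

    # channel networks: S/T kinases drive the global channel, Y kinases the pY one
    meta_g, edges_g, self_g, act_g = _build_channel(
        st_kinases, np.array(["S", "S", "S", "S", "T"]), cfg.n_sites_global,
        cfg.edges_per_kinase, cfg.predicted_fraction, r_net, "SUBG",
    )
    meta_y, edges_y, self_y, act_y = _build_channel(
        y_kinases, np.array(["Y"]), cfg.n_sites_py,
        cfg.edges_per_kinase, cfg.predicted_fraction, r_net, "SUBY",
    )
    network = KinaseSubstrateNetwork(
        edges=pd.concat([edges_g, edges_y], ignore_index=True),
        self_sites={**self_g, **self_y},
        activation_loop_sites={**act_g, **act_y},
    )

    # optional TP53-linked sites among orphan global substrate sites
    tp53_sites: list[str] = []
    if cfg.tp53_effect:
        orphan = [site_key(p, q, 1) for p, q, par in
                  zip(meta_g["protein"], meta_g["position"], meta_g["parents"]) if not par]
        tp53_sites = list(r_misc.choice(orphan, size=min(cfg.tp53_n_sites, len(orphan)),
                                        replace=False))

    sites_g, counts_g, logint_g = _simulate_channel_matrix(
        meta_g, activities, cfg, r_glob, GLOBAL_PST, samples, cellularity,
        tp53_mut, set(tp53_sites))
    sites_y, counts_y, logint_y = _simulate_channel_matrix(
        meta_y, activities, cfg, r_py, PY, samples, cellularity,
        tp53_mut, set(tp53_sites))
    true_log2 = {
        GLOBAL_PST: pd.DataFrame(logint_g, index=sites_g.data.index, columns=samples),
        PY: pd.DataFrame(logint_y, index=sites_y.data.index, columns=samples),
    }

    # pY channel dropout: a fixed fraction of samples lack pY data entirely
    n_drop = int(round(cfg.py_channel_dropout * cfg.n_samples))
    drop = set(r_misc.choice(samples, size=n_drop, replace=False)) if n_drop else set()
    py_samples = [s for s in samples if s not in drop]
    sites_y = SiteMatrix(sites_y.data[py_samples], sites_y.meta, PY)
    counts_y = counts_y[py_samples]

    # survival: exponential, log-hazard = beta * standardized prognostic activity
    a_prog = activities.loc[cfg.prognostic_kinase]
    z = (a_prog - a_prog.mean()) / a_prog.std(ddof=0)
    rate = np.log(2.0) / OS_BASELINE_MEDIAN * np.exp(cfg.hazard_beta * z.values)
    t_event = r_clin.exponential(1.0 / rate)
    censored = r_clin.random(cfg.n_samples) < cfg.censor_rate
    os_months = np.where(censored, t_event * r_clin.uniform(0.2, 1.0, cfg.n_samples), t_event)
    os_months = np.maximum(np.round(os_months, 1), 0.5)
    event = (~censored).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "os_months": os_months,
            "event_flag": event,
            "treatment_naive": naive,
            "cellularity_pct": cellularity,
            "kras_status": np.where(kras_mut, "mut", "WT"),
            "kras_allele": alleles,
            "tp53_status": np.where(tp53_mut.values.astype(bool), "mut", "WT"),
            "lysate_spectral_count": r_clin.poisson(50_000, cfg.n_samples),
        },
        index=samples,
    )

    # peptide evidence: one synthetic phosphopeptide per site, both channels
    counts_all = pd.concat([counts_g, counts_y.reindex(columns=samples, fill_value=0)])
    pep_index = [f"_pep({k})_" for k in counts_all.index]
    pep_meta = pd.DataFrame(
        {
            "protein": [k.split("|")[0] for k in counts_all.index],
            "position": [int(k.split("|")[1]) for k in counts_all.index],
        },
        index=pep_index,
    )
    pep_counts = counts_all.copy()
    pep_counts.index = pep_index
    pep_intens = pd.concat(
        [sites_g.data, sites_y.data.reindex(columns=samples)]
    )
    pep_intens.index = pep_index
    evidence = PeptideEvidence(counts=pep_counts, peptide_meta=pep_meta,
                               intensities=pep_intens)

    site_drivers = {
        site_key(p, q, 1): list(par)
        for p, q, par in zip(
            pd.concat([meta_g, meta_y])["protein"],
            pd.concat([meta_g, meta_y])["position"],
            pd.concat([meta_g, meta_y])["parents"],
        )
    }
    differential = [k for k, par in site_drivers.items() if par]

    truth = SyntheticTruth(
        subtype_labels=subtype,
        activities=activities,
        network=network,
        survival_months=pd.Series(os_months, index=samples),
        event_flag=pd.Series(event, index=samples),
        treatment_naive=pd.Series(naive, index=samples),
        kinase_subtype=kin_subtype,
        site_drivers=site_drivers,
        differential_sites=differential,
        tp53_sites=tp53_sites,
        spectral_counts=counts_all,
        true_log2=true_log2,
        config=cfg,
    )
    return truth, sites_g, sites_y, evidence, clinical


def write_evidence(ev: PeptideEvidence, path) -> None:
    """Emit an evidence-dialect TSV; counts >= 2 are split over two rows so
    that per-(peptide, sample) aggregation is actually exercised on re-read."""
    rows = []
    for pep in ev.counts.index:
        prot = ev.peptide_meta.loc[pep, "protein"]
        pos = ev.peptide_meta.loc[pep, "position"]
        for s in ev.counts.columns:
            c = int(ev.counts.loc[pep, s])
            if c == 0:
                continue
            parts = [c // 2, c - c // 2] if c >= 2 else [c]
            for p in parts:
                rows.append((pep, prot, pos, s, p))
    pd.DataFrame(
        rows, columns=["Modified sequence", "Proteins", "Positions", "Experiment", "MS/MS count"]
    ).to_csv(path, sep="\t", index=False)


def write_peptides(ev: PeptideEvidence, path) -> None:
    """Emit a modificationSpecificPeptides-dialect TSV (peptide intensities)."""
    df = pd.DataFrame(
        {
            "Modified sequence": ev.counts.index,
            "Proteins": ev.peptide_meta["protein"].values,
            "Positions": ev.peptide_meta["position"].values,
        }
    )
    if ev.intensities is not None:
        for s in ev.intensities.columns:
            df["Intensity " + s] = ev.intensities[s].fillna(0).values
    df.to_csv(path, sep="\t", index=False)


def write_fixture(truth: SyntheticTruth, sites_g: SiteMatrix, sites_y: SiteMatrix,
                  evidence: PeptideEvidence, clinical: pd.DataFrame, dir_path) -> dict:
    """Write the full cohort as MaxQuant-dialect text files plus a truth JSON.

    Returns the path map. Files round-trip losslessly through
    :mod:`phoskin.maxquant_io`."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites_global": d / "Phospho (STY)Sites_global.txt",
        "sites_py": d / "Phospho (STY)Sites_pY.txt",
        "peptides": d / "modificationSpecificPeptides.txt",
        "evidence": d / "evidence.txt",
        "network": d / "kinase_substrate_network.tsv",
        "clinical": d / "clinical.csv",
        "truth": d / "truth.json",
    }
    write_sites(sites_g, paths["sites_global"])
    write_sites(sites_y, paths["sites_py"])
    write_peptides(evidence, paths["peptides"])
    write_evidence(evidence, paths["evidence"])
    write_network(truth.network, paths["network"])
    clinical.to_csv(paths["clinical"], index=False)

    cfg = truth.config
    payload = {
        "subtype_labels": truth.subtype_labels.astype(int).to_dict(),
        "activities": {k: truth.activities.loc[k].round(6).to_dict()
                       for k in truth.activities.index},
        "survival_months": truth.survival_months.to_dict(),
        "event_flag": truth.event_flag.astype(int).to_dict(),
        "treatment_naive": truth.treatment_naive.astype(int).to_dict(),
        "kinase_subtype": truth.kinase_subtype,
        "site_drivers": truth.site_drivers,
        "differential_sites": truth.differential_sites,
        "tp53_sites": truth.tp53_sites,
        "spectral_counts": {k: {s: int(v) for s, v in row.items() if v}
                            for k, row in truth.spectral_counts.T.to_dict().items()},
        "config": dataclasses.asdict(cfg) if cfg else None,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
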