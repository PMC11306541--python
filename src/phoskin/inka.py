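"""Integrative inferred kinase activity (INKA) scoring.

For each kinase and analysis unit (a sample or a pooled group of samples)
four evidence arms are assembled from phosphopeptide spectral counts (or,
optionally, intensities):

* ``C_kin`` — counts on the kinase's own phosphosites (activation-loop sites
  excluded to avoid double counting),
* ``C_act`` — counts on its activation-loop sites,
* ``C_psp`` — counts summed over curated substrate sites,
* ``C_nwk`` — counts over predicted substrate sites passing the prediction
  score cutoff and not already covered by a curated edge of the same kinase.

Kinase-centric evidence K = C_kin + C_act and substrate-centric evidence
S = C_psp + C_nwk are integrated as the geometric mean I = sqrt(K * S).
Kinases with kinase-centric evidence only (S = 0) are reported in a separate
list rather than ranked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffstat import bh_adjust
from .maxquant_io import KinaseSubstrateNetwork, PeptideEvidence, SiteMatrix

log = logging.getLogger(__name__)

ARM_COLUMNS = ["C_kin", "C_act", "C_psp", "C_nwk"]


@dataclass
class EvidenceArms:
    """kinase x arm table of non-negative evidence for one unit."""

    unit: str
    arms: pd.DataFrame  # index kinase, columns ARM_COLUMNS

    def __post_init__(self) -> None:
        if (self.arms[ARM_COLUMNS] < 0).any().any():
            raise ValueError("evidence arms must be non-negative")


@dataclass
class InkaProfile:
    """Ranked kinase-activity profile for one unit and channel."""

    unit: str
    channel: str
    table: pd.DataFrame           # index kinase: arms, K, S, score, rank
    kinase_centric_only: pd.DataFrame = field(default_factory=pd.DataFrame)
    dp_pct: pd.Series | None = None


def site_evidence(sites: SiteMatrix, counts: PeptideEvidence | None,
                  use: str = "counts") -> pd.DataFrame:
    """Per-(protein, position) evidence matrix across samples.

    ``use="counts"`` attributes peptide spectral counts to sites via the
    peptide's (protein, position); ``use="intensity"`` sums site intensities.
    Index is a MultiIndex (protein, position)."""
    if use == "intensity" or counts is None:
        ev = sites.data.fillna(0.0).copy()
        ev.index = pd.MultiIndex.from_arrays(
            [sites.meta["protein"].values, sites.meta["position"].values]
        )
        return ev.groupby(level=[0, 1]).sum()
    ev = counts.counts.copy()
    ev.index = pd.MultiIndex.from_arrays(
        [counts.peptide_meta["protein"].values, counts.peptide_meta["position"].values]
    )
    ev = ev.groupby(level=[0, 1]).sum()
    # restrict to sites present in this channel's matrix
    keys = pd.MultiIndex.from_arrays(
        [sites.meta["protein"].values, sites.meta["position"].values]
    )
    ev = ev.loc[ev.index.isin(keys)]
    return ev.reindex(columns=sites.samples, fill_value=0)


def _sum_over(ev: pd.DataFrame, site_set, cols) -> float:
    idx = [s for s in site_set if s in ev.index]
    if not idx:
        return 0.0
    return float(ev.loc[idx, cols].to_numpy().sum())


def _kinase_site_sets(net: KinaseSubstrateNetwork, nwk_min_score: float) -> dict:
    """Per kinase the four site sets feeding the arms (curated wins over
    predicted for a site carrying both relation types from the same kinase)."""
    out = {}
    edges = net.edges
    by_kin = dict(tuple(edges.groupby("kinase"))) if len(edges) else {}
    for k in net.kinases:
        self_sites = set(net.self_sites.get(k, set()))
        act_sites = set(net.activation_loop_sites.get(k, set()))
        ek = by_kin.get(k)
        curated, predicted = set(), set()
        if ek is not None:
            for r in ek.itertuples():
                tgt = (r.substrate, int(r.position))
                if r.source == "curated":
                    curated.add(tgt)
                elif r.source == "predicted" and r.score >= nwk_min_score:
                    predicted.add(tgt)
        out[k] = (self_sites - act_sites, act_sites, curated, predicted - curated)
    return out


def build_evidence_arms(sites: SiteMatrix, counts: PeptideEvidence | None,
                        net: KinaseSubstrateNetwork, unit,
                        nwk_min_score: float = 2.0, use: str = "counts",
                        ev: pd.DataFrame | None = None) -> EvidenceArms:
    """Assemble the four evidence arms for one unit (a sample name or a list
    of samples, whose evidence is summed before arm construction).

    ``ev`` may carry a precomputed :func:`site_evidence` matrix to avoid
    re-aggregation across repeated calls."""
    if isinstance(unit, str):
        cols, unit_id = [unit], unit
    else:
        cols, unit_id = list(unit), "+".join(map(str, unit))
    missing = [c for c in cols if c not in sites.samples]
    if missing:
        raise ValueError(f"unknown samples {missing}")
    if ev is None:
        ev = site_evidence(sites, counts, use=use)
    ev = ev[cols]

    rows = {}
    for k, (kin_sites, act_sites, curated, predicted) in _kinase_site_sets(
        net, nwk_min_score
    ).items():
        rows[k] = [
            _sum_over(ev, kin_sites, cols),
            _sum_over(ev, act_sites, cols),
            _sum_over(ev, curated, cols),
            _sum_over(ev, predicted, cols),
        ]
    arms = pd.DataFrame.from_dict(rows, orient="index", columns=ARM_COLUMNS).sort_index()
    return EvidenceArms(unit=unit_id, arms=arms)


def inka_score(arms: EvidenceArms, channel: str = "pST") -> InkaProfile:
    """Score and rank kinases from their evidence arms.

    I = sqrt(K * S) with K = C_kin + C_act, S = C_psp + C_nwk. Kinases with
    K > 0 but S = 0 go to the kinase-centric-only list; kinases with no
    evidence at all are dropped. Ranks decrease with score; ties broken
    alphabetically by kinase id."""
    t = arms.arms.copy()
    t["K"] = t["C_kin"] + t["C_act"]
    t["S"] = t["C_psp"] + t["C_nwk"]
    t["score"] = np.sqrt(t["K"] * t["S"])
    kc_only = t[(t["K"] > 0) & (t["S"] == 0)].copy()
    ranked = t[t["score"] > 0].copy()
    order = ranked.reset_index().sort_values(
        ["score", "index"], ascending=[False, True], kind="mergesort"
    )["index"]
    ranked = ranked.loc[order]
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return InkaProfile(unit=arms.unit, channel=channel, table=ranked,
                       kinase_centric_only=kc_only)


def sample_profiles(sites: SiteMatrix, counts: PeptideEvidence | None,
                    net: KinaseSubstrateNetwork, nwk_min_score: float = 2.0,
                    use: str = "counts", channel: str = "pST") -> dict[str, InkaProfile]:
    """Per-sample INKA profiles for every sample of the matrix.

    Equivalent to calling :func:`build_evidence_arms` + :func:`inka_score`
    per sample; the arm sums are assembled in one vectorized pass."""
    ev = site_evidence(sites, counts, use=use)
    sets = _kinase_site_sets(net, nwk_min_score)
    arm_mats = {}  # arm -> kinase x sample DataFrame
    for a, arm in enumerate(ARM_COLUMNS):
        rows = {}
        for k, site_sets in sets.items():
            idx = [s for s in site_sets[a] if s in ev.index]
            rows[k] = ev.loc[idx].sum(axis=0) if idx else pd.Series(0.0, index=ev.columns)
        arm_mats[arm] = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return {
        s: inka_score(
            EvidenceArms(unit=s, arms=pd.DataFrame(
                {arm: arm_mats[arm][s] for arm in ARM_COLUMNS})),
            channel=channel,
        )
        for s in sites.samples
    }


def score_matrix(profiles: dict[str, InkaProfile]) -> pd.DataFrame:
    """kinase x sample matrix of INKA scores (0 where a kinase is unranked)."""
    cols = {u: p.table["score"] for u, p in profiles.items()}
    return pd.DataFrame(cols).fillna(0.0)


def group_profile(sites: SiteMatrix, counts: PeptideEvidence | None,
                  net: KinaseSubstrateNetwork, labels: pd.Series,
                  nwk_min_score: float = 2.0, use: str = "counts",
                  channel: str = "pST") -> dict:
    """Group-based profiles: evidence pooled (summed) over each group's
    samples before arm construction. Each kinase is annotated with its DP%:
    the percentage of the group's samples where it scores individually."""
    labels = pd.Series(labels).reindex(sites.samples).dropna()
    ev = site_evidence(sites, counts, use=use)
    per_sample = sample_profiles(sites, counts, net, nwk_min_score=nwk_min_score,
                                 use=use, channel=channel)
    smat = score_matrix(per_sample)
    out = {}
    for g in sorted(labels.unique()):
        members = list(labels.index[labels == g])
        if not members:
            raise ValueError(f"group {g!r} is empty")
        prof = inka_score(
            build_evidence_arms(sites, counts, net, members,
                                nwk_min_score=nwk_min_score, use=use, ev=ev),
            channel=channel,
        )
        present = smat.reindex(index=prof.table.index, columns=members).fillna(0.0) > 0
        prof.dp_pct = (100.0 * present.sum(axis=1) / len(members)).round(1)
        prof.table = prof.table.assign(dp_pct=prof.dp_pct)
        prof.unit = str(g)
        out[g] = prof
    return out


def top_n(profile: InkaProfile, n: int = 20) -> pd.DataFrame:
    """The first ``n`` kinases by rank (all of them, with a note, if fewer
    are scored)."""
    if n > len(profile.table):
        log.info("top_n: only %d kinases scored (requested %d)", len(profile.table), n)
    return profile.table.head(n).copy()


def compare_profiles(smat: pd.DataFrame, labels: pd.Series,
                     min_group: int = 2) -> pd.DataFrame:
    """Per-kinase two-group Mann–Whitney comparison of per-sample INKA scores
    with BH adjustment. ``smat`` is kinase x sample; kinases that are zero in
    all samples of both groups (or groups below ``min_group``) are skipped."""
    from scipy import stats

    labels = pd.Series(labels).reindex(smat.columns).dropna()
    gs = sorted(labels.unique())
    if len(gs) != 2:
        raise ValueError("compare_profiles expects exactly 2 groups")
    a_cols = labels.index[labels == gs[0]]
    b_cols = labels.index[labels == gs[1]]
    if len(a_cols) < min_group or len(b_cols) < min_group:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for k in smat.index:
        a, b = smat.loc[k, a_cols].to_numpy(), smat.loc[k, b_cols].to_numpy()
        if (a == 0).all() and (b == 0).all():
            continue
        if np.array_equal(np.sort(a), np.sort(b)):
            u, p = np.nan, 1.0
        else:
            method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({"kinase": k, "U": u, "p": p,
                     "median_diff": float(np.median(b) - np.median(a)),
                     "higher_in": gs[1] if np.median(b) > np.median(a) else gs[0]})
    rep = pd.DataFrame(rows).set_index("kinase")
    if len(rep):
        rep["q"] = bh_adjust(rep["p"].to_numpy())
    return rep
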