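"""Single-sample weighted rank enrichment (ssGSEA-style) and phosphosite
signature enrichment keyed by flanking windows (PTM-SEA-style).

The enrichment score of a signature in one ranked profile is the integrated
difference between the weighted in-set ECDF (weights |r|^alpha) and the
unweighted out-of-set ECDF. Gene-level signatures are scored on per-sample
values or on a pre-ranked metric; site-level signatures are keyed by the
15-mer flanking window, deduplicated by maximal row-sum intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maxquant_io import SiteMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureSet:
    """A named feature set (gene symbols, or 15-mer flank windows for site
    signatures). Size bounds are enforced at scoring time, after intersecting
    with the available keys."""

    name: str
    members: frozenset
    description: str = ""
    min_size: int = 5
    max_size: int = 1000

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} has no members")


@dataclass
class EnrichmentResult:
    es: pd.DataFrame                    # signature x unit
    normalized: bool = False
    skipped: dict = field(default_factory=dict)   # signature -> reason
    cluster_means: pd.DataFrame | None = None


def ssgsea_score(values: pd.Series, sig: SignatureSet, alpha: float = 0.25) -> float:
    """Enrichment score of ``sig`` in one profile of key -> value.

    Keys are ranked by value descending (ties broken by key order); the score
    integrates P_in(i) - P_out(i) over all ranks, where P_in weights in-set
    keys by |value|^alpha and P_out steps uniformly over out-of-set keys.
    A signature covering every key scores 0 by convention.
    """
    values = values.dropna()
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 keys")
    in_set = values.index.isin(sig.members)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"signature {sig.name!r} has no overlap with the profile")
    if n_in == n:
        return 0.0
    if values.nunique() == 1:
        log.warning("ssgsea_score: all values tied; ES = 0")
        return 0.0
    order = pd.DataFrame({"v": -values.values, "k": values.index}).sort_values(
        ["v", "k"], kind="mergesort"
    ).index
    v = np.abs(values.values[order]) ** alpha
    mask = in_set[order]
    w_in = np.where(mask, v, 0.0)
    denom = w_in.sum()
    if denom == 0:
        # all in-set values are exactly zero: fall back to uniform in-set steps
        w_in = mask.astype(float)
        denom = w_in.sum()
    p_in = np.cumsum(w_in) / denom
    p_out = np.cumsum(~mask) / (n - n_in)
    return float(np.sum(p_in - p_out))


def score_profile(values: pd.Series, sigs, alpha: float = 0.25):
    """Score many signatures on one profile, applying the size bounds after
    intersecting with available keys. Returns (Series sig -> ES, skipped)."""
    out, skipped = {}, {}
    avail = set(values.dropna().index)
    for sig in sigs:
        k = len(avail & set(sig.members))
        if k < sig.min_size or k > sig.max_size:
            skipped[sig.name] = f"effective size {k} outside [{sig.min_size}, {sig.max_size}]"
            continue
        out[sig.name] = ssgsea_score(values, sig, alpha=alpha)
    return pd.Series(out, dtype=float), skipped


def ssgsea_matrix(m: pd.DataFrame, sigs, alpha: float = 0.25) -> EnrichmentResult:
    """Per-sample ssGSEA over a key x sample matrix (missing keys are dropped
    per sample before ranking)."""
    cols = {}
    skipped: dict = {}
    for s in m.columns:
        es, sk = score_profile(m[s], sigs, alpha=alpha)
        cols[s] = es
        skipped.update(sk)
    es = pd.DataFrame(cols)
    return EnrichmentResult(es=es, skipped=skipped)


def preranked_score(metric: pd.Series, sigs, alpha: float = 1.0) -> EnrichmentResult:
    """Enrichment of signatures in a single pre-ranked metric (e.g. the signed
    -log10 P from the differential test), weighted with alpha = 1."""
    es, skipped = score_profile(metric, sigs, alpha=alpha)
    return EnrichmentResult(es=es.to_frame("preranked"), skipped=skipped)


def dedup_by_window(m: SiteMatrix) -> pd.DataFrame:
    """Collapse the site matrix to one row per flanking window, keeping the
    entry with the largest row-sum intensity; returns a window x sample
    matrix."""
    win = m.meta["window"]
    bad = win.str.len() != 15
    if bad.any():
        raise ValueError(f"flanking windows must be 15-mers ({int(bad.sum())} malformed)")
    rowsum = m.data.sum(axis=1, skipna=True)
    pick = (
        pd.DataFrame({"window": win.values, "rowsum": rowsum.values, "key": m.data.index})
        .sort_values(["window", "rowsum", "key"], ascending=[True, False, True],
                     kind="mergesort")
        .drop_duplicates("window")
    )
    out = m.data.loc[pick["key"]]
    out.index = pick["window"].values
    return out


def ptm_sea_score(m: SiteMatrix, site_sigs, alpha: float = 0.25) -> EnrichmentResult:
    """PTM-SEA-style scoring: deduplicate by flanking window, then run
    per-sample ssGSEA with windows as keys on the (normalized) intensities."""
    mat = dedup_by_window(m)
    return ssgsea_matrix(np.log2(mat.mask(mat <= 0)), site_sigs, alpha=alpha)


def average_by_cluster(res: EnrichmentResult, labels: pd.Series) -> pd.DataFrame:
    """Arithmetic mean of per-sample enrichment scores within each cluster."""
    labels = pd.Series(labels)
    missing = [s for s in res.es.columns if s not in labels.index or pd.isna(labels[s])]
    if missing:
        raise ValueError(f"unlabeled samples: {missing[:5]}")
    means = res.es.T.groupby(labels.reindex(res.es.columns)).mean().T
    res.cluster_means = means
    return means
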