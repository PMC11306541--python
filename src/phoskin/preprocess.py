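"""Normalization, feature filtering and QC for site matrices.

Channel-specific normalization follows label-free practice: the global pS/T
(IMAC) channel is scaled per sample to equalize median observed site
intensity; the pY IP channel is scaled per sample by total lysate spectral
count. Feature filtering combines a data-presence (DP) threshold with
selection of the most variable features by median absolute deviation (MAD).
Missing values are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .maxquant_io import GLOBAL_PST, PY, SiteMatrix


@dataclass
class FilterSpec:
    """Feature-filter settings: DP fraction (0.10 or 1.00 in the standard
    workflow), MAD top fraction (0.10 default; 0.20 for a kinome-focused
    view) and whether values enter downstream analyses on log2 scale."""

    dp_fraction: float = 0.10
    mad_top_fraction: float = 0.10
    log2_transform: bool = True

    def __post_init__(self) -> None:
        for name in ("dp_fraction", "mad_top_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def _frame(m) -> pd.DataFrame:
    return m.data if isinstance(m, SiteMatrix) else m


def _wrap(m, data: pd.DataFrame):
    if isinstance(m, SiteMatrix):
        return SiteMatrix(data, m.meta.loc[data.index].copy(), m.channel)
    return data


def normalize_median_site(m: SiteMatrix) -> SiteMatrix:
    """Median-site normalization for the global pS/T channel.

    Each sample is scaled multiplicatively so that its median observed site
    intensity equals the across-sample median of per-sample medians; missing
    entries stay missing."""
    if m.channel != GLOBAL_PST:
        raise ValueError("median-site normalization applies to the global pS/T channel")
    med = m.data.median(axis=0, skipna=True)
    if med.isna().any():
        bad = med.index[med.isna()][0]
        raise ValueError(f"sample {bad!r} has no observed values")
    target = float(med.median())
    return SiteMatrix(m.data * (target / med), m.meta.copy(), m.channel)


def normalize_total_count(m: SiteMatrix, lysate_counts: pd.Series) -> SiteMatrix:
    """Total-lysate-spectral-count normalization for the pY channel.

    Sample *s* is scaled by mean(totals) / totals[s]."""
    if m.channel != PY:
        raise ValueError("total-count normalization applies to the pY channel")
    totals = pd.Series(lysate_counts).reindex(m.samples)
    if totals.isna().any() or (totals <= 0).any():
        bad = totals.index[totals.isna() | (totals <= 0)][0]
        raise ValueError(f"sample {bad!r} has no positive lysate spectral count")
    factors = totals.mean() / totals
    return SiteMatrix(m.data * factors, m.meta.copy(), m.channel)


def filter_data_presence(m, fraction: float):
    """Keep features observed in at least ``fraction`` of samples (inclusive)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    df = _frame(m)
    frac_obs = df.notna().sum(axis=1) / df.shape[1]
    return _wrap(m, df.loc[frac_obs >= fraction])


def select_most_variable_mad(m, top_fraction: float):
    """Select the ceil(top_fraction * n_features) features with the largest
    MAD (median absolute deviation over observed values). Ties broken by
    feature key order, so selection is deterministic."""
    df = _frame(m)
    if df.shape[0] < 1:
        raise ValueError("need at least one feature")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    mad = (df.sub(df.median(axis=1, skipna=True), axis=0)).abs().median(axis=1, skipna=True)
    n_keep = int(np.ceil(top_fraction * df.shape[0]))
    order = pd.DataFrame({"mad": -mad.values, "key": df.index}).sort_values(
        ["mad", "key"], kind="mergesort"
    )
    keep = df.index[order.index[:n_keep]]
    return _wrap(m, df.loc[keep])


def log2_prepare(m):
    """log2-transform observed values; missing entries are preserved."""
    df = _frame(m)
    if (df < 0).any().any():
        raise ValueError("negative intensities cannot be log-transformed")
    return _wrap(m, np.log2(df.mask(df == 0)))


def mad_per_feature(m) -> pd.Series:
    df = _frame(m)
    return (df.sub(df.median(axis=1, skipna=True), axis=0)).abs().median(axis=1, skipna=True)


def qc_correlations(m: SiteMatrix, clinical: pd.DataFrame) -> dict:
    """QC summary: per-sample identification counts, Spearman of counts vs
    tumor cellularity, and the sample–sample Pearson matrix on the complete
    (100% DP) feature subset."""
    if len(m.samples) < 3:
        raise ValueError("need at least 3 samples")
    counts = m.data.notna().sum(axis=0)
    out: dict = {"site_counts": counts}
    cell = clinical["cellularity_pct"].reindex(m.samples) if "cellularity_pct" in clinical else None
    if cell is not None and cell.notna().all():
        if counts.nunique() == 1 or cell.nunique() == 1:
            out["cellularity_spearman"] = {"rho": np.nan, "p": np.nan,
                                           "note": "constant vector; rho undefined"}
        else:
            rho, p = stats.spearmanr(counts.values, cell.values)
            out["cellularity_spearman"] = {"rho": float(rho), "p": float(p)}
    complete = m.data.dropna(axis=0)
    out["n_complete_features"] = int(complete.shape[0])
    if complete.shape[0] >= 2:
        out["sample_pearson"] = complete.corr(method="pearson")
    return out
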