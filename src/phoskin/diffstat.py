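"""Moderated differential statistics with BH adjustment and fold-change gates.

Two- and three-group tests use an empirical-Bayes moderated t / F statistic:
per-feature pooled variances are shrunk toward a prior variance s0^2 with
prior degrees of freedom d0, both fitted by moment matching on the log
variances across features (Smyth-style). Features are tested on observed
values only; no imputation. The signed -log10 P metric feeds pre-ranked
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

log = logging.getLogger(__name__)


@dataclass
class DiffResult:
    """Per-feature moderated-test results.

    ``table`` columns: per-group means (``mean_<g>``), ``log2_fc`` (two-group:
    difference of log2 group means; >2 groups: the largest-magnitude pairwise
    difference, signed), ``stat`` (moderated t or F), ``p``, ``q`` (BH),
    ``s2_g``, ``d_g``, ``tested``. ``d0``/``s02`` are the fitted prior.
    """

    table: pd.DataFrame
    d0: float
    s02: float
    groups: list[str]
    statistic: str  # "t" or "F"


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit (d0, s0^2) by matching moments of log s^2 across features.

    Uses e_g = log(s2_g) - digamma(d_g/2) + log(d_g/2); the excess variance of
    e_g over its sampling variance identifies d0, its mean identifies s0^2.
    Returns (inf, exp(mean e)) when the observed spread is no larger than the
    sampling spread (complete shrinkage)."""
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("not enough features with positive residual dof to fit the prior")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    excess = np.mean((e - e_mean) ** 2 * s2.size / (s2.size - 1.0)) - np.mean(
        special.polygamma(1, df / 2.0)
    )
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s02


def moderated_test(m: pd.DataFrame, groups: pd.Series, d0_override: float | None = None) -> DiffResult:
    """Moderated two-group t or multi-group F test per feature (rows of ``m``,
    log2 scale; columns = samples; ``groups`` maps sample -> label).

    Features with fewer than 2 observed values in any group are reported
    untested. ``d0_override`` fixes the prior dof (0 recovers the classic
    test, inf gives complete shrinkage)."""
    groups = pd.Series(groups).reindex(m.columns).dropna()
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    cols = {g: m.columns.intersection(groups.index[groups == g]) for g in labels}
    for g, c in cols.items():
        if len(c) == 0:
            raise ValueError(f"group {g!r} has no samples")

    ngr = {g: m[cols[g]].notna().sum(axis=1) for g in labels}
    means = {g: m[cols[g]].mean(axis=1) for g in labels}
    ss = {
        g: ((m[cols[g]].sub(means[g], axis=0)) ** 2).sum(axis=1, min_count=1)
        for g in labels
    }
    n_tot = sum(ngr.values())
    d_g = n_tot - len(labels)
    ss_within = sum(s.fillna(0.0) for s in ss.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_g = ss_within / d_g.replace(0, np.nan)
    tested = pd.concat(ngr, axis=1).min(axis=1) >= 2

    if not tested.any():
        raise ValueError("no feature has >= 2 observed values in every group")
    n_skipped = int((~tested).sum())
    if n_skipped:
        log.info("moderated_test: %d features untested (min group n < 2)", n_skipped)

    if d0_override is not None:
        d0 = float(d0_override)
        s02 = float(np.nanmedian(s2_g[tested])) if not np.isfinite(d0) or d0 > 0 else 0.0
        if np.isfinite(d0) and d0 > 0:
            # prior variance still from the data when only dof is pinned
            _, s02 = fit_variance_prior(s2_g[tested].to_numpy(), d_g[tested].to_numpy(dtype=float))
    else:
        try:
            d0, s02 = fit_variance_prior(s2_g[tested].to_numpy(), d_g[tested].to_numpy(dtype=float))
        except ValueError:
            log.warning("prior fit failed; falling back to the classic (unmoderated) test")
            d0, s02 = 0.0, 0.0

    if np.isfinite(d0) and d0 > 0:
        s2_post = (d0 * s02 + d_g * s2_g) / (d0 + d_g)
    elif d0 == 0:
        s2_post = s2_g.copy()
    else:  # d0 = inf
        s2_post = pd.Series(s02, index=m.index)
    df_total = np.where(np.isfinite(d0), d0 + d_g, 1e9)

    table = pd.DataFrame(index=m.index)
    for g in labels:
        table[f"mean_{g}"] = means[g]
    if len(labels) == 2:
        g1, g2 = labels
        delta = means[g2] - means[g1]
        se = np.sqrt(s2_post * (1.0 / ngr[g1] + 1.0 / ngr[g2]))
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = delta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        table["log2_fc"] = delta
        table["stat"] = tstat
        statistic = "t"
    else:
        grand = sum(ngr[g] * means[g].fillna(0.0) for g in labels) / n_tot
        ss_between = sum(ngr[g] * (means[g] - grand) ** 2 for g in labels)
        df1 = len(labels) - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            fstat = (ss_between / df1) / s2_post
        p = stats.f.sf(fstat, df1, df_total)
        # fold-change gate: largest-magnitude pairwise difference, signed
        mean_mat = pd.concat(means, axis=1)
        diffs = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                diffs.append(mean_mat[labels[j]] - mean_mat[labels[i]])
        diffs = pd.concat(diffs, axis=1)
        idx = diffs.abs().to_numpy().argmax(axis=1)
        table["log2_fc"] = diffs.to_numpy()[np.arange(len(diffs)), idx]
        table["stat"] = fstat
        statistic = "F"

    p = pd.Series(p, index=m.index)
    p[~tested] = np.nan
    table.loc[~tested, ["stat", "log2_fc"]] = np.nan
    table["p"] = p.clip(lower=np.finfo(float).tiny, upper=1.0)
    table.loc[~tested, "p"] = np.nan
    q = pd.Series(np.nan, index=m.index)
    q[tested] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["q"] = q
    table["s2_g"] = s2_g
    table["d_g"] = d_g
    table["tested"] = tested
    return DiffResult(table=table, d0=float(d0), s02=float(s02), groups=list(labels),
                      statistic=statistic)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def significant_features(res: DiffResult, q_max: float = 0.05, fc_min: float = 2.0,
                         use_q: bool = True) -> list[str]:
    """Features passing the adjusted-p and fold-change gates (both boundaries
    inclusive). ``fc_min`` is a ratio: the gate is |log2_fc| >= log2(fc_min).
    ``use_q=False`` gates on the unadjusted p instead (extreme-group
    contrasts)."""
    t = res.table
    pcol = t["q"] if use_q else t["p"]
    keep = (pcol <= q_max) & (t["log2_fc"].abs() >= np.log2(fc_min)) & t["tested"]
    return list(t.index[keep.fillna(False)])


def rank_metric(res: DiffResult) -> pd.Series:
    """Signed rank metric for pre-ranked enrichment: (-log10 p) * sign(log2_fc)."""
    t = res.table
    p = t["p"].copy()
    zero = p == 0
    if zero.any():
        log.warning("rank_metric: %d zero p-values capped", int(zero.sum()))
        p[zero] = np.finfo(float).tiny
    r = -np.log10(p) * np.sign(t["log2_fc"])
    return r.dropna()


def nonparametric_tests(values: pd.Series, groups: pd.Series) -> dict:
    """Mann–Whitney U (two groups; exact for n <= 8 per group) and/or
    Kruskal–Wallis H (>= 3 groups)."""
    groups = pd.Series(groups).reindex(values.index).dropna()
    values = values.reindex(groups.index).dropna()
    groups = groups.reindex(values.index)
    arrs = [values[groups == g].to_numpy() for g in sorted(groups.unique())]
    if any(a.size == 0 for a in arrs) or len(arrs) < 2:
        raise ValueError("need at least 2 non-empty groups")
    out: dict = {}
    if len(arrs) == 2:
        method = "exact" if max(a.size for a in arrs) <= 8 else "asymptotic"
        u = stats.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided", method=method)
        out["mannwhitney"] = {"U": float(u.statistic), "p": float(u.pvalue)}
    if len(arrs) >= 2:
        if all(np.array_equal(a, arrs[0]) for a in arrs[1:]) or np.all(
            np.concatenate(arrs) == np.concatenate(arrs)[0]
        ):
            out["kruskal"] = {"H": 0.0, "p": 1.0}
        else:
            kw = stats.kruskal(*arrs)
            out["kruskal"] = {"H": float(kw.statistic), "p": float(kw.pvalue)}
    return out
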