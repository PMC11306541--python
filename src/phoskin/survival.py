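"""Survival association of kinase activities and phosphosites.

Per-kinase Spearman correlation of INKA scores with overall survival, a
bimodal kernel-density cutoff separating short from long survivors,
Kaplan–Meier summaries with log-rank comparison, and extreme-group
differential contrasts. OS is correlated directly (no censoring adjustment);
a caveat is logged whenever censored samples enter a correlation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .diffstat import DiffResult, moderated_test, significant_features

log = logging.getLogger(__name__)

KDE_GRID_POINTS = 512


@dataclass
class SurvivalAssoc:
    """Per-kinase Spearman association with overall survival."""

    table: pd.DataFrame  # index kinase: rho, p, n_used, direction
    naive_only: bool = False


@dataclass
class OutcomeGroups:
    cutoff_months: float
    short_ids: list[str]
    long_ids: list[str]
    treatment_naive_only: bool = True


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho at small n (<= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(ry):
        if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12:
            count += 1
    return count / total


def spearman_survival(smat: pd.DataFrame, clinical: pd.DataFrame,
                      naive_only: bool = False, min_observed: int = 3) -> SurvivalAssoc:
    """Spearman correlation of per-sample kinase scores (kinase x sample) with
    os_months. Exact permutation p for n <= 9, t-approximation otherwise.
    Kinases scored (> 0) in fewer than ``min_observed`` samples are skipped;
    constant score vectors are reported as not assessable."""
    samples = [s for s in smat.columns if s in clinical.index]
    if naive_only:
        samples = [s for s in samples if clinical.loc[s, "treatment_naive"] == 1]
    if len(samples) < 3:
        raise ValueError("need at least 3 samples with scores and survival")
    os_m = clinical.loc[samples, "os_months"].astype(float)
    if "event_flag" in clinical and (clinical.loc[samples, "event_flag"] == 0).any():
        log.info("spearman_survival: censored samples included; OS correlated as observed")
    rows = {}
    for k in smat.index:
        v = smat.loc[k, samples].astype(float)
        n_obs = int((v > 0).sum())
        if n_obs < min_observed:
            continue
        if v.nunique() == 1 or os_m.nunique() == 1:
            rows[k] = {"rho": np.nan, "p": np.nan, "n_used": len(samples),
                       "direction": "not-assessable"}
            continue
        rho = stats.spearmanr(v.values, os_m.values).statistic
        if len(samples) <= 9:
            p = _spearman_exact_p(v.values, os_m.values)
        else:
            p = stats.spearmanr(v.values, os_m.values).pvalue
        rows[k] = {
            "rho": float(rho),
            "p": float(p),
            "n_used": len(samples),
            "direction": "poor-survival" if rho < 0 else "better-survival",
        }
    return SurvivalAssoc(table=pd.DataFrame.from_dict(rows, orient="index"),
                         naive_only=naive_only)


#: a density peak must reach this fraction of the global density maximum to
#: count as a mode; keeps negligible bumps in a sparse survival tail from
#: being mistaken for a second component
MODE_PROMINENCE = 0.10


def bimodal_cutoff(os_months, bw_method: str = "silverman") -> float | None:
    """Kernel-density cutoff between short and long survival.

    Gaussian KDE (Silverman bandwidth) on OS over a 512-point grid; with two
    or more modes (local maxima reaching >= 10% of the density peak), returns
    the position of the lowest density minimum between the two largest modes,
    else None."""
    x = np.asarray(os_months, dtype=float)
    if x.size < 10:
        raise ValueError("need n >= 10 for a density-based cutoff; set one manually")
    kde = stats.gaussian_kde(x, bw_method=bw_method)
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, KDE_GRID_POINTS)
    d = kde(grid)
    interior = np.arange(1, KDE_GRID_POINTS - 1)
    maxima = interior[(d[interior] > d[interior - 1]) & (d[interior] >= d[interior + 1])]
    maxima = maxima[d[maxima] >= MODE_PROMINENCE * d.max()]
    if maxima.size < 2:
        return None
    top2 = maxima[np.argsort(d[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    between = np.arange(lo + 1, hi)
    if between.size == 0:
        return None
    cut = grid[between[np.argmin(d[between])]]
    return float(cut)


def define_outcome_groups(clinical: pd.DataFrame, cutoff: float,
                          naive_only: bool = True) -> OutcomeGroups:
    """Short (os <= cutoff) vs long (os > cutoff) survivors, optionally among
    treatment-naive patients only."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    df = clinical
    if naive_only:
        df = df[df["treatment_naive"] == 1]
        if df.empty:
            raise ValueError("no treatment-naive samples")
    short = list(df.index[df["os_months"] <= cutoff])
    long_ = list(df.index[df["os_months"] > cutoff])
    if not short or not long_:
        raise ValueError(f"empty outcome group at cutoff {cutoff} "
                         f"(short={len(short)}, long={len(long_)})")
    log.info("outcome groups: %d short vs %d long at %.1f months",
             len(short), len(long_), cutoff)
    return OutcomeGroups(cutoff_months=float(cutoff), short_ids=short,
                         long_ids=long_, treatment_naive_only=naive_only)


def km_estimate(times, events) -> dict:
    """Kaplan–Meier product-limit estimate.

    Returns the step function (event times and survival probabilities) and
    the median survival (NaN = not reached)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times <= 0).any():
        raise ValueError("times must be > 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_["KM_estimate"]
    median = kmf.median_survival_time_
    return {
        "times": sf.index.to_numpy(dtype=float),
        "survival": sf.to_numpy(dtype=float),
        "median": float(median) if np.isfinite(median) else np.nan,
    }


def km_at(km: dict, t: float) -> float:
    """S(t) from a km_estimate result (right-continuous step function)."""
    idx = np.searchsorted(km["times"], t, side="right") - 1
    return float(km["survival"][max(idx, 0)])


def logrank(times1, events1, times2, events2) -> dict:
    """Two-group log-rank test (chi-square, 1 dof)."""
    t1, t2 = np.asarray(times1, float), np.asarray(times2, float)
    e1, e2 = np.asarray(events1), np.asarray(events2)
    if np.array_equal(t1, t2) and np.array_equal(e1, e2):
        return {"statistic": 0.0, "p": 1.0}
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return {"statistic": float(res.test_statistic), "p": float(res.p_value)}


def extreme_group_diff(m: pd.DataFrame, groups: OutcomeGroups,
                       p_max: float = 0.05, fc_min: float = 2.0) -> tuple[DiffResult, list[str]]:
    """Differential features between short and long survivors.

    Uses the moderated test with gates on the *unadjusted* p (<= p_max) and
    |log2 FC| >= log2(fc_min) — the convention for small extreme-group
    contrasts, deliberately laxer than the FDR-gated subtype analysis."""
    labels = pd.Series(
        {**{s: "short" for s in groups.short_ids}, **{s: "long" for s in groups.long_ids}}
    )
    labels = labels.reindex([c for c in m.columns if c in labels.index]).dropna()
    if (labels == "short").sum() < 2 or (labels == "long").sum() < 2:
        raise ValueError("need at least 2 samples per outcome group")
    res = moderated_test(m[labels.index], labels)
    sig = significant_features(res, q_max=p_max, fc_min=fc_min, use_q=False)
    return res, sig
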