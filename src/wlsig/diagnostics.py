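"""Weight-trajectory diagnostics.

Identifies "regainers" (above-median overall losers who rebound more
than 4% of baseline weight during the 2-8-month maintenance phase),
correlates overall with maintenance weight loss, and tests — with a
Jonckheere-Terpstra ordered-trend test — whether high-AUC runs carried
fewer regainers in their training sets than low-AUC runs.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def trajectory_stats(weights: pd.DataFrame, regain_cutoff: float = -4.0) -> pd.DataFrame:
    """Per-sample weight-loss percentages and the regainer flag.

    All percentages are denominated in baseline weight: overall WL% =
    100 (w0 - w8)/w0, maintenance WL% = 100 (w2 - w8)/w0. A regainer
    loses more than the cohort-median overall WL% yet has maintenance
    WL% below ``regain_cutoff`` (default -4, i.e. regained > 4%).
    """
    w = weights[["weight_0m", "weight_2m", "weight_8m"]].astype(float)
    if (w.dropna() <= 0).any().any():
        raise ValueError("weights must be positive")
    overall = 100.0 * (w["weight_0m"] - w["weight_8m"]) / w["weight_0m"]
    maintenance = 100.0 * (w["weight_2m"] - w["weight_8m"]) / w["weight_0m"]
    med = overall.median()
    out = pd.DataFrame({
        "overall_wl_pct": overall,
        "maintenance_wl_pct": maintenance,
        "regain_pct": -maintenance,
        "regainer": (overall > med) & (maintenance < regain_cutoff),
        "missing": w.isna().any(axis=1),
    })
    out.loc[out["missing"], "regainer"] = False
    return out


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-approximation P."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined")
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---- Jonckheere-Terpstra --------------------------------------------
def _jt_statistic(groups) -> float:
    """J = sum over ordered group pairs of Mann-Whitney counts (ties 0.5)."""
    j = 0.0
    for gi, gj in itertools.combinations(groups, 2):
        a = np.asarray(gi, float)[:, None]
        b = np.asarray(gj, float)[None, :]
        j += np.sum(a < b) + 0.5 * np.sum(a == b)
    return float(j)


def _jt_null_moments(groups):
    ns = np.array([len(g) for g in groups], dtype=float)
    N = ns.sum()
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    _vals, t = np.unique(pooled, return_counts=True)
    t = t.astype(float)
    mean = (N * N - np.sum(ns ** 2)) / 4.0
    term1 = (N * (N - 1) * (2 * N + 5)
             - np.sum(ns * (ns - 1) * (2 * ns + 5))
             - np.sum(t * (t - 1) * (2 * t + 5))) / 72.0
    term2 = (np.sum(ns * (ns - 1) * (ns - 2)) * np.sum(t * (t - 1) * (t - 2))
             / (36.0 * N * (N - 1) * (N - 2)))
    term3 = (np.sum(ns * (ns - 1)) * np.sum(t * (t - 1))
             / (8.0 * N * (N - 1)))
    return mean, term1 + term2 + term3


def _partitions(values, sizes):
    """All assignments of pooled values (by index) into groups of given sizes."""
    idx = tuple(range(len(values)))

    def rec(remaining, sizes):
        if not sizes:
            yield []
            return
        for combo in itertools.combinations(remaining, sizes[0]):
            rest = tuple(i for i in remaining if i not in set(combo))
            for tail in rec(rest, sizes[1:]):
                yield [combo] + tail

    return rec(idx, sizes)


def jonckheere_terpstra(groups, alternative: str = "increasing",
                        exact_max_n: int = 12) -> tuple[float, float]:
    """Jonckheere-Terpstra trend test across >= 2 ordered groups.

    P by full permutation enumeration when the pooled sample size is at
    most ``exact_max_n``, otherwise by the tie-corrected normal
    approximation. ``alternative`` is "increasing", "decreasing" or
    "two-sided" (trend along the given group order).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 ordered groups, each with >= 1 value")
    if alternative not in {"increasing", "decreasing", "two-sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    j_obs = _jt_statistic(groups)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)

    if N <= exact_max_n:
        ge = le = total = 0
        for assign in _partitions(pooled, sizes):
            perm_groups = [pooled[list(ix)] for ix in assign]
            j = _jt_statistic(perm_groups)
            total += 1
            ge += j >= j_obs - 1e-12
            le += j <= j_obs + 1e-12
        p_inc = ge / total
        p_dec = le / total
    else:
        mean, var = _jt_null_moments(groups)
        if var <= 0:
            return j_obs, 1.0
        sd = np.sqrt(var)
        # continuity-corrected tie-adjusted normal approximation
        p_inc = float(stats.norm.sf((j_obs - 0.5 - mean) / sd))
        p_dec = float(stats.norm.cdf((j_obs + 0.5 - mean) / sd))
    if alternative == "increasing":
        p = p_inc
    elif alternative == "decreasing":
        p = p_dec
    else:
        p = min(1.0, 2.0 * min(p_inc, p_dec))
    return j_obs, float(p)


# ---- run stratification ---------------------------------------------
def stratify_runs_by_auc(aucs, train_id_lists, regainer_ids,
                         threshold: float = 0.6):
    """Per-run regainer counts in training sets, split by the AUC threshold.

    Returns (low_auc_counts, high_auc_counts) ordered for the
    "regainer burden decreases in the high-AUC group" alternative, or
    None (with a warning) when a stratum is empty or there are no
    regainers to count.
    """
    aucs = np.asarray(aucs, dtype=float)
    regainer_ids = set(regainer_ids)
    counts = np.array([len(regainer_ids & set(ids)) for ids in train_id_lists])
    valid = ~np.isnan(aucs)
    lo = counts[valid & (aucs <= threshold)]
    hi = counts[valid & (aucs > threshold)]
    if len(lo) == 0 or len(hi) == 0:
        warnings.warn("one AUC stratum is empty: trend test skipped")
        return None
    if counts.sum() == 0:
        warnings.warn("no regainers in any training set: trend test degenerate")
        return None
    return lo, hi


def regainer_trend_test(aucs, train_id_lists, regainer_ids,
                        threshold: float = 0.6) -> tuple[float, float] | None:
    """JT test that high-AUC runs trained on fewer regainers (decreasing trend)."""
    strata = stratify_runs_by_auc(aucs, train_id_lists, regainer_ids, threshold)
    if strata is None:
        return None
    lo, hi = strata
    return jonckheere_terpstra([lo, hi], alternative="decreasing")
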