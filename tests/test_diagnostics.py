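"""Trajectory statistics, correlation, and the Jonckheere-Terpstra test."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wlsig.diagnostics import (jonckheere_terpstra, pearson_corr,
                               regainer_trend_test, stratify_runs_by_auc,
                               trajectory_stats)


# ---- trajectories ----------------------------------------------------
def test_trajectory_stats_definitions():
    w = pd.DataFrame({
        "weight_0m": [100.0, 100.0, 100.0, 100.0],
        "weight_2m": [85.0, 92.0, 96.0, 97.0],
        "weight_8m": [90.0, 92.0, 94.0, 97.0]},
        index=list("abcd"))
    out = trajectory_stats(w)
    assert out.loc["a", "overall_wl_pct"] == pytest.approx(10.0)
    assert out.loc["a", "maintenance_wl_pct"] == pytest.approx(-5.0)
    # median overall WL is 7: 'a' is above it and regained > 4 -> regainer
    assert bool(out.loc["a", "regainer"])
    assert not out.loc["b", "regainer"]      # maintenance 0
    assert not out.loc["c", "regainer"]      # kept losing during maintenance
    # identity: overall - maintenance = LCD-phase loss (same denominator)
    lcd = 100.0 * (w["weight_0m"] - w["weight_2m"]) / w["weight_0m"]
    assert np.allclose(out["overall_wl_pct"] - out["maintenance_wl_pct"], lcd)


def test_trajectory_missing_weights_flagged():
    w = pd.DataFrame({"weight_0m": [100.0, 100.0, 100.0],
                      "weight_2m": [90.0, np.nan, 91.0],
                      "weight_8m": [85.0, 85.0, 84.0]}, index=list("abc"))
    out = trajectory_stats(w)
    assert bool(out.loc["b", "missing"]) and not bool(out.loc["b", "regainer"])


# ---- Pearson ---------------------------------------------------------
def test_pearson_oracle_and_trivials(rng):
    x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
    y = np.array([0.5, 1.9, 3.1, 5.0, 6.2])
    r, p = pearson_corr(x, y)
    r_hand = (np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1)))
    assert r == pytest.approx(r_hand, abs=1e-12)
    assert pearson_corr(x, x)[0] == pytest.approx(1.0)
    assert pearson_corr(x, -x)[0] == pytest.approx(-1.0)


# ---- Jonckheere-Terpstra ---------------------------------------------
def _jt_exact_oracle(groups, alternative):
    """Brute-force full-permutation P, written independently."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]

    def jt(gs):
        total = 0.0
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                for a in gs[i]:
                    for b in gs[j]:
                        total += (a < b) + 0.5 * (a == b)
        return total

    obs = jt([list(g) for g in groups])
    count_ge = count_le = total = 0
    idx = list(range(len(pooled)))
    for perm in set(itertools.permutations(idx)):
        gs, pos = [], 0
        for s in sizes:
            gs.append([pooled[i] for i in perm[pos:pos + s]])
            pos += s
        stat = jt(gs)
        total += 1
        count_ge += stat >= obs - 1e-12
        count_le += stat <= obs + 1e-12
    return (count_ge / total) if alternative == "increasing" else (count_le / total)


def test_jt_reduces_to_mann_whitney_for_two_groups():
    g1, g2 = [1.0, 5.0, 3.0], [4.0, 6.0, 8.0, 2.0]
    stat, _p = jonckheere_terpstra([g1, g2])
    u = stats.mannwhitneyu(g2, g1, alternative="greater").statistic
    assert stat == pytest.approx(u)


def test_jt_exact_matches_independent_enumeration():
    groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    stat, p = jonckheere_terpstra(groups, alternative="increasing")
    assert stat == 12.0           # fully ordered: all 12 cross-pairs concordant
    assert p == pytest.approx(_jt_exact_oracle(groups, "increasing"), abs=1e-12)
    # a less regular configuration, with ties
    groups2 = [[2.0, 2.0, 5.0], [4.0, 1.0], [6.0, 3.0]]
    for alt in ("increasing", "decreasing"):
        _s, p2 = jonckheere_terpstra(groups2, alternative=alt)
        assert p2 == pytest.approx(_jt_exact_oracle(groups2, alt), abs=1e-12)


def test_jt_normal_approximation_close_to_exact(rng):
    for _ in range(8):
        groups = [rng.integers(0, 5, size=4).astype(float) for _ in range(3)]
        _s, p_exact = jonckheere_terpstra(groups, alternative="decreasing")
        _s, p_norm = jonckheere_terpstra(groups, alternative="decreasing",
                                         exact_max_n=0)
        assert abs(p_exact - p_norm) < 0.05


def test_jt_degenerate_inputs():
    _s, p = jonckheere_terpstra([[2.0, 2.0], [2.0, 2.0], [2.0]],
                                alternative="increasing")
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        jonckheere_terpstra([[1.0]])


# ---- stratification --------------------------------------------------
def test_stratify_runs_by_auc_cases():
    aucs = [0.4, 0.55, 0.7, 0.8]
    trains = [["a", "b"], ["a", "c"], ["c", "d"], ["d", "e"]]
    strata = stratify_runs_by_auc(aucs, trains, {"a"}, threshold=0.6)
    lo, hi = strata
    assert list(lo) == [1, 1] and list(hi) == [0, 0]
    with pytest.warns(UserWarning, match="empty"):
        assert stratify_runs_by_auc(aucs, trains, {"a"}, threshold=0.9) is None
    with pytest.warns(UserWarning, match="no regainers"):
        assert stratify_runs_by_auc(aucs, trains, {"zz"}, threshold=0.6) is None


def test_regainer_trend_detects_planted_concentration(rng):
    """Regainers forced into low-AUC training sets -> decreasing trend P < 0.05."""
    ids = [f"s{i}" for i in range(60)]
    regainers = set(ids[:6])
    aucs, trains = [], []
    for run in range(60):
        chosen = list(rng.choice(ids, size=48, replace=False))
        burden = len(regainers & set(chosen))
        aucs.append(0.78 - 0.05 * burden + rng.normal(0, 0.02))
        trains.append(chosen)
    stat, p = regainer_trend_test(aucs, trains, regainers, threshold=0.6)
    assert p < 0.05
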