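"""Filtering, TMM, log-CPM and batch-adjustment contracts.

The TMM check re-derives the factors with an independent step-by-step
transcription of the published trimmed-mean-of-M-values recipe (doubly
trimmed, inverse-variance-weighted mean of log-ratios against the
reference sample).
"""
import numpy as np
import pytest

from wlsig.matrix import CountMatrix
from wlsig.preprocess import (batch_adjust_counts, filter_low_counts,
                              lcpm_transform, tmm_factors)


# ---- filtering -------------------------------------------------------
def test_filter_strictly_greater_than_threshold():
    cm = CountMatrix(["g0", "g5", "g6"], ["a", "b"],
                     np.array([[0, 0], [2, 3], [3, 3]]))
    kept = filter_low_counts(cm, min_total=5)
    assert list(kept.gene_ids) == ["g6"]


def test_filter_identity_and_brute_force(rng):
    vals = rng.integers(0, 30, size=(10, 4))
    cm = CountMatrix([f"g{i}" for i in range(10)], list("abcd"), vals)
    kept = filter_low_counts(cm, min_total=5)
    expected = [f"g{i}" for i in range(10) if sum(vals[i]) > 5]
    assert list(kept.gene_ids) == expected
    high = CountMatrix(["x", "y"], ["a", "b"], np.full((2, 2), 10))
    assert list(filter_low_counts(high).gene_ids) == ["x", "y"]


def test_filter_empty_result_errors():
    cm = CountMatrix(["g"], ["a", "b"], np.array([[1, 1]]))
    with pytest.raises(ValueError, match="no genes"):
        filter_low_counts(cm, min_total=5)


# ---- TMM -------------------------------------------------------------
def _tmm_oracle(y, logratio_trim=0.3, sum_trim=0.05):
    """Independent straight-line transcription of the TMM definition."""
    y = np.asarray(y, float)
    G, S = y.shape
    lib = y.sum(axis=0)
    # reference: upper quartile of scaled counts closest to the mean
    uq = [np.quantile(y[:, j] / lib[j], 0.75) for j in range(S)]
    ref = min(range(S), key=lambda j: abs(uq[j] - np.mean(uq)))
    factors = []
    for j in range(S):
        if j == ref:
            factors.append(1.0)
            continue
        M, A, w = [], [], []
        for g in range(G):
            if y[g, j] > 0 and y[g, ref] > 0:
                pj, pr = y[g, j] / lib[j], y[g, ref] / lib[ref]
                M.append(np.log2(pj / pr))
                A.append(0.5 * np.log2(pj * pr))
                w.append((lib[j] - y[g, j]) / (lib[j] * y[g, j])
                         + (lib[ref] - y[g, ref]) / (lib[ref] * y[g, ref]))
        M, A, w = map(np.array, (M, A, w))
        if np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(M)
        lo_l = int(np.floor(n * logratio_trim)) + 1
        hi_l = n + 1 - lo_l
        lo_s = int(np.floor(n * sum_trim)) + 1
        hi_s = n + 1 - lo_s
        rm = np.argsort(np.argsort(M)) + 1
        ra = np.argsort(np.argsort(A)) + 1
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors.append(2.0 ** f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def test_tmm_identical_and_scaled_columns_give_unit_factors():
    col = np.array([10, 20, 0, 5, 40, 100])
    same = CountMatrix([f"g{i}" for i in range(6)], ["a", "b"],
                       np.column_stack([col, col]))
    assert np.allclose(tmm_factors(same).tmm_factor, 1.0)
    doubled = CountMatrix([f"g{i}" for i in range(6)], ["a", "b"],
                          np.column_stack([col, 2 * col]))
    assert np.allclose(tmm_factors(doubled).tmm_factor, 1.0)


def test_tmm_matches_independent_hand_computation():
    y = np.array([[100, 150, 80], [20, 25, 10], [500, 400, 600],
                  [5, 50, 5], [1000, 900, 1100], [60, 70, 40]])
    cm = CountMatrix([f"g{i}" for i in range(6)], ["a", "b", "c"], y)
    got = tmm_factors(cm).tmm_factor
    assert np.allclose(got, _tmm_oracle(y), atol=1e-8)


def test_tmm_matches_oracle_on_random_matrices(rng):
    for _ in range(5):
        y = rng.negative_binomial(3, 0.02, size=(100, 5))
        cm = CountMatrix([f"g{i}" for i in range(100)],
                         [f"s{j}" for j in range(5)], y)
        assert np.allclose(tmm_factors(cm).tmm_factor, _tmm_oracle(y), atol=1e-8)


def test_tmm_scale_invariance_and_geomean(rng):
    y = rng.negative_binomial(3, 0.02, size=(200, 4))
    cm = CountMatrix([f"g{i}" for i in range(200)], list("abcd"), y)
    base = tmm_factors(cm)
    assert abs(np.exp(np.mean(np.log(base.tmm_factor))) - 1.0) < 1e-9
    scaled_vals = y.copy()
    scaled_vals[:, 2] *= 3
    scaled = tmm_factors(CountMatrix(cm.gene_ids, cm.sample_ids, scaled_vals))
    # invariance is approximate, not exact: the inverse-variance weights
    # (binomial asymptotics) depend on absolute counts, so scaling one
    # column perturbs the weighting of its log-ratios slightly
    assert np.allclose(scaled.tmm_factor, base.tmm_factor, atol=0.02)


def test_tmm_all_zero_sample_errors():
    cm = CountMatrix(["g1", "g2"], ["a", "b"], np.array([[1, 0], [2, 0]]))
    with pytest.raises(ValueError, match="b"):
        tmm_factors(cm)


# ---- log-CPM ---------------------------------------------------------
def test_lcpm_formula_and_monotonicity(rng):
    y = rng.integers(0, 500, size=(3, 2))
    cm = CountMatrix(["g1", "g2", "g3"], ["a", "b"], y)
    nf = tmm_factors(cm)
    got = lcpm_transform(cm, nf, prior=0.5).to_numpy()
    eff = nf.lib_size * nf.tmm_factor
    expected = np.log2((y + 0.5) / (eff[None, :] + 1.0) * 1e6)
    assert np.allclose(got, expected, atol=1e-10)
    assert np.isfinite(got).all()
    # strictly increasing in the count for a fixed sample
    bumped = y.copy()
    bumped[0, 0] += 1
    got2 = lcpm_transform(CountMatrix(cm.gene_ids, cm.sample_ids, bumped),
                          nf).to_numpy()
    assert got2[0, 0] > got[0, 0]


def test_lcpm_zero_count_value():
    # a zero count in a library of ~1e6 sits at ~ -1.0 with prior 0.5
    y = np.zeros((2, 2), dtype=int)
    y[1, :] = 10 ** 6 - 0  # library ~ 1e6
    cm = CountMatrix(["z", "big"], ["a", "b"], y)
    nf = tmm_factors(cm)
    val = lcpm_transform(cm, nf).to_numpy()[0, 0]
    assert abs(val - np.log2(0.5 / (1e6 + 1) * 1e6)) < 1e-6


# ---- batch adjustment ------------------------------------------------
def test_batch_adjust_single_batch_is_identity(rng):
    y = rng.integers(0, 100, size=(20, 10))
    cm = CountMatrix([f"g{i}" for i in range(20)],
                     [f"s{j}" for j in range(10)], y)
    adj = batch_adjust_counts(cm, np.repeat("C1", 10))
    assert np.array_equal(adj.values, cm.values)


def test_batch_adjust_removes_planted_fold_change(rng):
    n, G = 100, 120
    batch = np.array(["A"] * 50 + ["B"] * 50)
    mu = np.exp(rng.normal(4, 1, size=G))
    r = 10.0
    muM = np.tile(mu[:, None], (1, n))
    muM[:, 50:] *= 2.0
    y = rng.negative_binomial(r, r / (r + muM))
    cm = CountMatrix([f"g{i}" for i in range(G)], [f"s{j}" for j in range(n)], y)
    adj = batch_adjust_counts(cm, batch)
    means_a = adj.values[:, :50].mean(axis=1)
    means_b = adj.values[:, 50:].mean(axis=1)
    ratio = np.median(means_b / np.maximum(means_a, 1e-9))
    assert 0.9 < ratio < 1.1
    # shape/ids/non-negativity preserved
    assert adj.values.shape == cm.values.shape
    assert (adj.values >= 0).all()
    assert list(adj.gene_ids) == list(cm.gene_ids)
    # idempotent within tolerance
    twice = batch_adjust_counts(adj, batch)
    rel = np.abs(twice.values - adj.values).sum() / adj.values.sum()
    assert rel < 0.05


def test_batch_adjust_zero_gene_and_errors(rng):
    y = rng.integers(0, 50, size=(5, 6))
    y[2] = 0
    cm = CountMatrix([f"g{i}" for i in range(5)], [f"s{j}" for j in range(6)], y)
    adj = batch_adjust_counts(cm, np.array(["A", "A", "A", "B", "B", "B"]))
    assert (adj.values[2] == 0).all()
    with pytest.raises(ValueError, match="fewer than 2"):
        batch_adjust_counts(cm, np.array(["A", "A", "A", "A", "A", "B"]))
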