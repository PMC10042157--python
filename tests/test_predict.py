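"""Resampling, labelling, SVM, AUC/DeLong and the per-run loop."""
import numpy as np
import pandas as pd
import pytest

from wlsig.predict import (ModelConfig, RunFeatureExtractor, assign_wl_labels,
                           delong_ci, evaluate_gene_sets, make_resamples,
                           run_model, score_auc, train_linear_svm)
from wlsig.signature import GeneSignature
from wlsig.synthdata import CohortBundle


# ---- resampling ------------------------------------------------------
def test_make_resamples_sizes_and_determinism():
    ids = [f"s{i}" for i in range(10)]
    plan = make_resamples(ids, n_runs=20, train_fraction=0.8, seed=3)
    for train, test in plan.splits:
        assert len(train) == 8 and len(test) == 2
        assert sorted(train + test) == sorted(ids)
    plan2 = make_resamples(ids, n_runs=20, train_fraction=0.8, seed=3)
    assert plan.splits == plan2.splits
    with pytest.raises(ValueError):
        make_resamples(ids, train_fraction=1.2)
    with pytest.raises(ValueError):
        make_resamples(ids[:5])


def test_resample_test_frequency_law_of_large_numbers():
    ids = [f"s{i}" for i in range(50)]
    plan = make_resamples(ids, n_runs=1000, train_fraction=0.8, seed=9)
    freq = pd.Series(0.0, index=ids)
    for _train, test in plan.splits:
        freq[test] += 1
    freq /= 1000
    assert (np.abs(freq - 0.2) < 0.05).all()


# ---- labels ----------------------------------------------------------
def test_wl_label_median_split():
    samples = pd.DataFrame({
        "weight_0m": [100.0, 100.0, 100.0, 100.0],
        "weight_8m": [95.0, 92.0, 90.0, 88.0]},
        index=["a", "b", "c", "d"])
    lab = assign_wl_labels(samples, ["a", "b", "c", "d"])
    assert lab.median == 9.0
    assert lab.labels.to_dict() == {"a": 0, "b": 0, "c": 1, "d": 1}
    # all equal -> none strictly above the median -> all low-WL
    flat = pd.DataFrame({"weight_0m": [100.0] * 4, "weight_8m": [90.0] * 4},
                        index=list("abcd"))
    lab2 = assign_wl_labels(flat, list("abcd"))
    assert (lab2.labels == 0).all()


# ---- SVM -------------------------------------------------------------
def test_svm_separable_ordering_and_duplicate_column(rng):
    x = np.linspace(-2, 2, 40)[:, None]
    y = (x[:, 0] > 0).astype(int)
    model = train_linear_svm(x, y, ModelConfig())
    test_x = rng.normal(size=(15, 1))
    scores = model.decision_values(test_x)
    assert (np.argsort(scores) == np.argsort(test_x[:, 0])).all()
    # duplicating a feature column leaves the decision ordering essentially
    # unchanged (the L2 penalty splits the weight over the two copies, which
    # mildly rescales that feature, so agreement is near- rather than exact)
    from scipy.stats import spearmanr
    X2 = rng.normal(size=(60, 3))
    y2 = (X2[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
    m1 = train_linear_svm(X2, y2)
    m2 = train_linear_svm(np.column_stack([X2, X2[:, 0]]), y2)
    t = rng.normal(size=(25, 3))
    s1 = m1.decision_values(t)
    s2 = m2.decision_values(np.column_stack([t, t[:, 0]]))
    assert spearmanr(s1, s2).statistic > 0.99
    with pytest.raises(ValueError, match="single class"):
        train_linear_svm(x, np.zeros(40))


def test_svm_null_features_auc_centred_at_half(rng):
    aucs = []
    for _ in range(30):
        Xtr = rng.normal(size=(160, 10))
        ytr = (rng.random(160) < 0.5).astype(int)
        Xte = rng.normal(size=(40, 10))
        yte = (rng.random(40) < 0.5).astype(int)
        model = train_linear_svm(Xtr, ytr)
        aucs.append(score_auc(model.decision_values(Xte), yte))
    assert abs(np.mean(aucs) - 0.5) < 0.05


# ---- AUC -------------------------------------------------------------
def _auc_bruteforce(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples_and_pair_counting(rng):
    assert score_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75
    assert score_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
    assert score_auc([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5
    for _ in range(200):
        n = int(rng.integers(4, 30))
        scores = rng.integers(0, 6, size=n).astype(float)  # forces ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        assert score_auc(scores, labels) == pytest.approx(
            _auc_bruteforce(scores, labels), abs=1e-12)


def test_auc_label_swap_symmetry(rng):
    scores = rng.normal(size=50)
    labels = (rng.random(50) < 0.4).astype(int)
    assert score_auc(scores, labels) == pytest.approx(
        1.0 - score_auc(scores, 1 - labels), abs=1e-12)


# ---- DeLong ----------------------------------------------------------
def test_delong_degenerate_and_contains_point():
    scores = np.r_[np.ones(5), np.zeros(5)]
    labels = np.r_[np.ones(5, int), np.zeros(5, int)]
    with pytest.warns(UserWarning, match="perfect separation"):
        lo, hi = delong_ci(scores, labels)
    assert (lo, hi) == (1.0, 1.0)
    rng = np.random.default_rng(0)
    for _ in range(20):
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        if y.sum() < 2 or y.sum() > 38:
            continue
        lo, hi = delong_ci(s, y)
        auc = score_auc(s, y)
        assert lo <= auc <= hi


# ---- per-run loop ----------------------------------------------------
def test_run_model_deterministic_and_reports(small_cohort, small_plan, small_extractor):
    sig = GeneSignature("lipid", sorted(small_cohort.truth.module_gene_ids["lipid"]))
    rep1 = run_model(small_cohort, sig, small_plan, ModelConfig(), small_extractor)
    rep2 = run_model(small_cohort, sig, small_plan, ModelConfig(), small_extractor)
    assert np.allclose(rep1.aucs, rep2.aucs, equal_nan=True)
    valid = rep1.aucs[~np.isnan(rep1.aucs)]
    assert rep1.median_auc == np.median(valid)
    assert rep1.max_auc == valid.max()
    assert rep1.delong[0] <= rep1.max_auc <= rep1.delong[1]
    # planted signature separates the classes well above chance
    assert rep1.median_auc > 0.6
    with pytest.raises(ValueError, match="absent"):
        run_model(small_cohort, GeneSignature("x", ["NOPE"]), small_plan)


def test_training_side_blind_to_test_data(small_cohort, small_plan):
    """Poisoning the test subsample must leave training features unchanged."""
    run = 0
    train_ids, test_ids = small_plan.splits[run]
    genes = list(small_cohort.counts.gene_ids[:12])
    ext = RunFeatureExtractor(small_cohort, small_plan)
    base_train = ext.features(run, "train", genes)

    poisoned_counts = small_cohort.counts.to_frame().copy()
    poisoned_counts.loc[:, test_ids] = (poisoned_counts.loc[:, test_ids] * 7) + 13
    poisoned_samples = small_cohort.samples.copy()
    poisoned_samples.loc[test_ids, ["weight_0m", "weight_2m", "weight_8m"]] = [200.0, 199.0, 198.0]
    from wlsig.matrix import CountMatrix
    poisoned = CohortBundle(CountMatrix.from_frame(poisoned_counts),
                            poisoned_samples, small_cohort.clinical, None)
    ext2 = RunFeatureExtractor(poisoned, small_plan)
    assert np.allclose(ext2.features(run, "train", genes).to_numpy(),
                       base_train.to_numpy())
    lab1 = assign_wl_labels(small_cohort.samples, train_ids)
    lab2 = assign_wl_labels(poisoned.samples, train_ids)
    assert (lab1.labels == lab2.labels).all()
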