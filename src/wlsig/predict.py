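"""Resampling architecture, WL labelling, linear SVM, AUC and DeLong CI.

One "run" = one Monte-Carlo 80/20 split of the cohort. Within a run the
training and testing subsamples are normalized and batch-adjusted
independently of each other, labels are assigned by the subset-median
weight-loss split, a linear SVM (cost 1) is trained on standardized
signature-gene log-CPM features, and the test-set AUC is recorded. The
report summarises the per-run AUCs by their median and maximum, with a
DeLong 95% CI at the best run.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .diffexp import DesignSpec, run_de
from .enrich import TermAnnotation, build_map, enrich_terms
from .matrix import CountMatrix
from .nbglm import moment_dispersion
from .preprocess import batch_adjust_counts, filter_low_counts, tmm_factors
from .signature import GeneSignature, SelectionParams, label_component, pca_top_contributors
from .synthdata import CohortBundle

log = logging.getLogger(__name__)


# ---- resampling plan -------------------------------------------------
@dataclass
class ResamplePlan:
    """Monte-Carlo cross-validation splits (default 100 x 80/20)."""

    sample_ids: list
    n_runs: int
    train_fraction: float
    seed: int
    splits: list = field(default_factory=list)  # list of (train_ids, test_ids)


def make_resamples(sample_ids, n_runs: int = 100, train_fraction: float = 0.8,
                   seed: int = 0) -> ResamplePlan:
    """Independent uniform 80/20 splits without stratification."""
    ids = np.asarray(list(sample_ids), dtype=object)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 samples to resample")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    splits = []
    for _ in range(n_runs):
        perm = rng.permutation(n)
        splits.append((list(ids[perm[:n_train]]), list(ids[perm[n_train:]])))
    return ResamplePlan(list(ids), n_runs, train_fraction, seed, splits)


# ---- weight-loss labels ----------------------------------------------
@dataclass
class WLLabels:
    """Overall weight-loss %, the subset-median cutoff, and binary labels."""

    wl_pct: pd.Series
    median: float
    labels: pd.Series      # 1 = high-WL (strictly above the subset median)


def assign_wl_labels(samples: pd.DataFrame, subset_ids) -> WLLabels:
    """Median-split high-WL/low-WL labels within a sample subset.

    WL% = 100 * (weight_0m - weight_8m) / weight_0m; high-WL requires WL%
    strictly above the subset median. Samples with missing weights are
    excluded with a warning.
    """
    sub = samples.loc[list(subset_ids)]
    w = sub[["weight_0m", "weight_8m"]]
    missing = w.isna().any(axis=1)
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} sample(s) with missing weights")
        sub = sub[~missing]
    if sub.empty:
        raise ValueError("no samples with complete weights in subset")
    wl = 100.0 * (sub["weight_0m"] - sub["weight_8m"]) / sub["weight_0m"]
    med = float(wl.median())
    return WLLabels(wl, med, (wl > med).astype(int))


# ---- SVM -------------------------------------------------------------
@dataclass
class ModelConfig:
    kernel: str = "linear"
    cost: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")


class LinearSVMModel:
    """Soft-margin linear SVM wrapper carrying the training scaler."""

    def __init__(self, svc: SVC, mean: np.ndarray, sd: np.ndarray):
        self._svc, self._mean, self._sd = svc, mean, sd

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self._mean) / self._sd
        return self._svc.decision_function(Xs)


def train_linear_svm(features: np.ndarray, labels, config: ModelConfig = None) -> LinearSVMModel:
    """Train the classifier on standardized features (training statistics)."""
    config = config or ModelConfig()
    X = np.asarray(features, float)
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if config.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    svc = SVC(kernel=config.kernel, C=config.cost)
    svc.fit((X - mean) / sd, y)
    return LinearSVMModel(svc, mean, sd)


# ---- AUC + DeLong ----------------------------------------------------
def score_auc(decision_values, labels) -> float:
    """ROC AUC = (concordant + 0.5 * tied pairs) / (n_pos * n_neg).

    Computed through the rank-sum (Mann-Whitney) identity, which counts
    ties as half-concordant.
    """
    s = np.asarray(decision_values, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to score an AUC")
    ranks = stats.rankdata(s)
    r_pos = ranks[y == 1].sum()
    m, n = len(pos), len(neg)
    return float((r_pos - m * (m + 1) / 2.0) / (m * n))


def delong_ci(decision_values, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong nonparametric CI for the AUC from placement-value variances."""
    s = np.asarray(decision_values, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong CI needs >= 2 samples per class")
    # placement values
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0:
        warnings.warn("zero DeLong variance (perfect separation): degenerate CI")
        return float(auc), float(auc)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


# ---- per-run feature extraction (cached) -----------------------------
class RunFeatureExtractor:
    """Caches per-run, per-subsample normalized/adjusted log-CPM features.

    Normalization (TMM + library sizes) and NB batch adjustment are
    computed within each 80% and 20% subsample independently. Library
    sizes and TMM factors come from the unadjusted counts (the
    adjustment preserves totals to rounding); the NB quantile-map
    adjustment itself is applied lazily to the genes a model actually
    uses, which keeps the 100-run x 100-null-set loop tractable.
    """

    def __init__(self, bundle: CohortBundle, plan: ResamplePlan,
                 adjust: bool = True, prior: float = 0.5):
        self.bundle = bundle
        self.plan = plan
        self.adjust = adjust
        self.prior = prior
        self._cache: dict = {}

    def _part_state(self, run: int, part: str):
        key = (run, part)
        if key in self._cache:
            return self._cache[key]
        train_ids, test_ids = self.plan.splits[run]
        ids = train_ids if part == "train" else test_ids
        counts = self.bundle.counts.subset_samples(ids)
        nf = tmm_factors(counts)
        lib = nf.effective_lib_size
        disp = moment_dispersion(counts.values,
                                 nf.lib_size / np.exp(np.mean(np.log(nf.lib_size))))
        # centers left with < 2 samples in this subsample cannot anchor a
        # batch coefficient; pool them with the modal center
        meta = self.bundle.samples.loc[ids]
        centers = meta["center"].to_numpy(object).copy()
        sizes = pd.Series(centers).value_counts()
        small = sizes.index[sizes < 2]
        if len(small):
            centers[np.isin(centers, small)] = sizes.idxmax()
        state = {"ids": ids, "counts": counts, "eff_lib": lib, "disp": disp,
                 "centers": centers, "adjusted": {}}
        self._cache[key] = state
        return state

    def features(self, run: int, part: str, gene_ids) -> pd.DataFrame:
        """Samples x genes log2-CPM feature matrix for one run subsample."""
        state = self._part_state(run, part)
        counts: CountMatrix = state["counts"]
        gene_ids = list(gene_ids)
        meta = self.bundle.samples.loc[state["ids"]]
        single_batch = len(np.unique(state["centers"])) < 2
        if self.adjust and not single_batch:
            missing = [g for g in gene_ids if g not in state["adjusted"]]
            if missing:
                sub = counts.subset_genes(missing)
                idx = counts.gene_index(missing)
                adj = batch_adjust_counts(
                    sub, state["centers"], sex=meta["sex"].to_numpy(),
                    age=meta["age"].to_numpy(), dispersions=state["disp"][idx])
                for i, g in enumerate(missing):
                    state["adjusted"][g] = adj.values[i]
            vals = np.stack([state["adjusted"][g] for g in gene_ids])
        else:
            vals = counts.subset_genes(gene_ids).values
        lcpm = np.log2((vals + self.prior)
                       / (state["eff_lib"][None, :] + 2 * self.prior) * 1e6)
        return pd.DataFrame(lcpm.T, index=pd.Index(state["ids"], name="sample_id"),
                            columns=gene_ids)


# ---- model evaluation ------------------------------------------------
@dataclass
class ModelReport:
    """Per-run AUCs and their summary for one feature set."""

    class_name: str
    aucs: np.ndarray                 # NaN where the run was skipped
    median_auc: float
    max_auc: float
    best_run: int
    delong: tuple
    n_skipped: int
    empirical_p: float | None = None

    def to_dict(self) -> dict:
        return {"class": self.class_name,
                "aucs": [None if np.isnan(a) else float(a) for a in self.aucs],
                "median_auc": self.median_auc, "max_auc": self.max_auc,
                "best_run": self.best_run,
                "delong_ci": list(self.delong), "n_skipped": self.n_skipped,
                "empirical_p": self.empirical_p}


def _summarise(class_name, aucs, best_scores, best_labels, n_skipped) -> ModelReport:
    valid = aucs[~np.isnan(aucs)]
    if len(valid) == 0:
        raise ValueError("no run produced a valid AUC")
    best = int(np.nanargmax(aucs))
    ci = delong_ci(best_scores, best_labels)
    return ModelReport(class_name, aucs, float(np.median(valid)),
                       float(np.max(valid)), best, ci, n_skipped)


def evaluate_gene_sets(
    bundle: CohortBundle,
    gene_sets: dict,
    plan: ResamplePlan,
    config: ModelConfig = None,
    extractor: RunFeatureExtractor | None = None,
    extra_features: pd.DataFrame | None = None,
) -> dict:
    """Evaluate several gene sets on a shared resampling plan.

    gene_sets maps name -> gene list; the per-run adjusted features are
    computed once for the union of all sets. ``extra_features`` (samples
    x factors, e.g. clinical covariates) are appended to every set's
    feature matrix and standardized with training statistics like any
    other feature. Returns {name: ModelReport}.
    """
    config = config or ModelConfig()
    extractor = extractor or RunFeatureExtractor(bundle, plan)
    union: list = []
    seen = set()
    for genes in gene_sets.values():
        for g in genes:
            if g not in seen:
                union.append(g)
                seen.add(g)
    aucs = {name: np.full(plan.n_runs, np.nan) for name in gene_sets}
    best: dict = {name: (-np.inf, None, None) for name in gene_sets}
    n_skipped = 0
    for r, (train_ids, test_ids) in enumerate(plan.splits):
        lab_tr = assign_wl_labels(bundle.samples, train_ids)
        lab_te = assign_wl_labels(bundle.samples, test_ids)
        if lab_tr.labels.nunique() < 2 or lab_te.labels.nunique() < 2:
            n_skipped += 1
            log.info("run %d skipped: single-class subset", r)
            continue
        if union:
            Xtr_all = extractor.features(r, "train", union)
            Xte_all = extractor.features(r, "test", union)
        else:
            Xtr_all = pd.DataFrame(index=pd.Index(train_ids))
            Xte_all = pd.DataFrame(index=pd.Index(test_ids))
        if extra_features is not None:
            Xtr_all = pd.concat([Xtr_all, extra_features.loc[Xtr_all.index]], axis=1)
            Xte_all = pd.concat([Xte_all, extra_features.loc[Xte_all.index]], axis=1)
        ytr = lab_tr.labels.loc[Xtr_all.index].to_numpy()
        yte = lab_te.labels.loc[Xte_all.index].to_numpy()
        extra_cols = [] if extra_features is None else list(extra_features.columns)
        col_pos = {c: i for i, c in enumerate(Xtr_all.columns)}
        Xtr_np = np.ascontiguousarray(Xtr_all.to_numpy(float))
        Xte_np = np.ascontiguousarray(Xte_all.to_numpy(float))
        for name, genes in gene_sets.items():
            ci = np.array([col_pos[c] for c in list(genes) + extra_cols], dtype=int)
            model = train_linear_svm(Xtr_np[:, ci], ytr, config)
            scores = model.decision_values(Xte_np[:, ci])
            auc = score_auc(scores, yte)
            aucs[name][r] = auc
            if auc > best[name][0]:
                best[name] = (auc, scores, yte)
    return {name: _summarise(name, aucs[name], best[name][1], best[name][2], n_skipped)
            for name in gene_sets}


def run_model(bundle: CohortBundle, signature: GeneSignature, plan: ResamplePlan,
              config: ModelConfig = None,
              extractor: RunFeatureExtractor | None = None,
              extra_features: pd.DataFrame | None = None) -> ModelReport:
    """Full per-run loop for one signature; see module docstring."""
    missing = set(signature.genes) - set(bundle.counts.gene_ids)
    if missing:
        raise ValueError(f"signature genes absent from counts: {sorted(missing)[:5]}")
    reports = evaluate_gene_sets(bundle, {signature.class_name: list(signature.genes)},
                                 plan, config, extractor, extra_features)
    return reports[signature.class_name]


# ---- discovery phase -------------------------------------------------
@dataclass
class DiscoveryResult:
    """Per-class per-run gene selections plus run-level bookkeeping."""

    selections: dict              # class -> {run: ordered gene list}
    n_runs: int
    runs_without_significant: list
    class_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            self.class_counts = {c: len(r) for c, r in self.selections.items()}


def discover_features(
    bundle: CohortBundle,
    plan: ResamplePlan,
    annotation_terms: dict,
    params: SelectionParams = None,
    alpha_nominal: float = 0.01,
    min_total: int = 5,
    p_cut: float = 0.05,
    q_cut: float = 0.2,
    fdr_cut: float = 0.05,
    redundancy_cut: float = 0.7,
    edge_cut: float = 0.2,
    extractor: RunFeatureExtractor | None = None,
) -> DiscoveryResult:
    """Per-run DE -> enrichment map -> labelled-component PCA selection.

    For every run the training subsample is analysed: NB Wald DE at the
    nominal cutoff, hypergeometric enrichment over the filtered-gene
    universe, enrichment-map components, keyword class labels, and the
    top-10 PCA contributors of each labelled component's gene union.
    Runs yielding no significant term are recorded.
    """
    params = params or SelectionParams()
    extractor = extractor or RunFeatureExtractor(bundle, plan)
    selections: dict = {}
    no_sig: list = []
    for r, (train_ids, _test_ids) in enumerate(plan.splits):
        labels = assign_wl_labels(bundle.samples, train_ids)
        counts = filter_low_counts(bundle.counts.subset_samples(train_ids), min_total)
        meta = bundle.samples.loc[train_ids]
        design = DesignSpec(wl_class=labels.labels, sex=meta["sex"], age=meta["age"],
                            center=meta["center"], alpha_nominal=alpha_nominal)
        de = run_de(counts, design)
        degs = set(de.index[de["significant"]])
        annot = TermAnnotation.from_terms(annotation_terms, counts.gene_ids)
        table = enrich_terms(degs, annot, p_cut, q_cut, fdr_cut) if degs else None
        if table is None or not table["significant"].any():
            no_sig.append(r)
            continue
        emap = build_map(table, annot, redundancy_cut, edge_cut)
        labelled_this_run = set()
        for ci, comp in enumerate(emap.components):
            names = [annot.terms[t]["name"] for t in comp]
            cls = label_component(names, params)
            if cls == "unlabeled" or cls in labelled_this_run:
                continue  # components are ordered by best P; first labelled wins
            labelled_this_run.add(cls)
            genes = sorted(emap.component_gene_union(annot, ci))
            expr = extractor.features(r, "train", genes)
            top = pca_top_contributors(expr, params)
            selections.setdefault(cls, {})[r] = top
    return DiscoveryResult(selections, plan.n_runs, no_sig)
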