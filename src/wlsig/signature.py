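"""Gene-signature extraction from enrichment-map components.

Within a run, the genes of a labelled component are ranked by their PCA
contribution (eigenvalue-weighted squared loadings over the leading
components that explain >= 70% of the variance) and the top ten are
kept. Across the resampling runs the per-run selections are aggregated
by discovery frequency into a fixed signature per pathway class, and
signatures can be combined by set union/difference (e.g. Lipid + Virus,
Virus - Lipid).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# pathway-class keyword defaults: substrings of GO biological-process
# names characteristic of the lipid-metabolism, mitosis/meiosis and
# response-to-virus classes recovered by this analysis on real data
DEFAULT_CLASS_KEYWORDS: dict[str, list[str]] = {
    "Lipid": [
        "fatty acid", "fatty-acyl", "acyl-coa", "thioester", "triglyceride",
        "lipid metabolic", "bisphosphate metabolic", "demethylation",
        "retinoic acid", "retinol", "steroid", "secondary alcohol biosynthetic",
        "xenobiotic", "drug metabolic", "ribose phosphate",
    ],
    "Mitosis": [
        "mitotic", "meiotic", "chromosome", "chromatid", "nuclear division",
        "cell cycle", "cytokinesis", "spindle", "microtubule",
        "chromosome condensation", "cholesterol metabolic", "drug catabolic",
        "hormone metabolic", "secondary alcohol metabolic",
    ],
    "Virus": ["virus", "viral", "estrogen metabolic"],
}


@dataclass
class SelectionParams:
    """Knobs of the per-run gene selection."""

    variance_threshold: float = 0.70
    n_genes: int = 10
    class_keywords: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CLASS_KEYWORDS.items()})
    standardize: bool = True
    eigen_weighted: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


@dataclass
class GeneSignature:
    """Ordered gene list with per-gene discovery frequencies (%)."""

    class_name: str
    genes: list
    frequencies: list = field(default_factory=list)
    provenance: list = field(default_factory=list)   # run ids where the class appeared

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.frequencies and any(f == f and not 0 <= f <= 100
                                    for f in self.frequencies):
            raise ValueError("frequencies must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {"class": self.class_name, "genes": list(self.genes),
                "frequencies": list(self.frequencies),
                "provenance": list(self.provenance)}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSignature":
        return cls(d["class"], list(d["genes"]), list(d.get("frequencies", [])),
                   list(d.get("provenance", [])))


def pca_contributions(expr: pd.DataFrame, params: SelectionParams) -> pd.Series:
    """Per-gene PCA contribution over the leading >= threshold-variance PCs.

    expr is samples x genes. Genes are standardized first (constant genes
    dropped with a warning); contribution_g = sum_{j<=d} lambda_j *
    loading_{g,j}^2 / sum_{j<=d} lambda_j where d is the smallest number
    of leading PCs whose cumulative explained variance reaches the
    threshold. Contributions over the selected PCs sum to 1.
    """
    X = expr.to_numpy(float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 gene")
    if np.isnan(X).any():
        raise ValueError("missing values in expression matrix")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes are constant")
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} constant gene(s) before PCA")
    cols = expr.columns[keep]
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    if params.standardize:
        Xc = Xc / sd[keep]
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = svals ** 2 / (X.shape[0] - 1)          # eigenvalues
    evr = lam / lam.sum()
    d = int(np.searchsorted(np.cumsum(evr), params.variance_threshold - 1e-12) + 1)
    d = min(d, len(lam))
    load2 = Vt[:d].T ** 2                         # squared loadings, genes x d
    if params.eigen_weighted:
        contrib = (load2 * lam[:d]).sum(axis=1) / lam[:d].sum()
    else:
        contrib = load2.mean(axis=1)
    return pd.Series(contrib, index=cols).sort_values(ascending=False)


def pca_top_contributors(expr: pd.DataFrame, params: SelectionParams) -> list:
    """Top ``params.n_genes`` genes by PCA contribution (all if fewer)."""
    contrib = pca_contributions(expr, params)
    return list(contrib.index[: params.n_genes])


def label_component(component_term_names, params: SelectionParams) -> str:
    """Assign a pathway-class label by keyword vote over term names.

    The class whose keywords match the most term names wins
    (case-insensitive substring match); ties or no match give
    "unlabeled".
    """
    names = [str(n).lower() for n in component_term_names]
    if not names:
        raise ValueError("component has no term names")
    scores = {}
    for cls, keywords in params.class_keywords.items():
        kw = [k.lower() for k in keywords]
        scores[cls] = sum(1 for n in names if any(k in n for k in kw))
    best = max(scores.values(), default=0)
    winners = [c for c, s in scores.items() if s == best]
    if best == 0 or len(winners) != 1:
        return "unlabeled"
    return winners[0]


def aggregate_signature(per_run_selections: dict, class_name: str,
                        params: SelectionParams, total_runs: int) -> GeneSignature:
    """Frequency-aggregate per-run gene selections into one signature.

    frequency = 100 * (#runs featuring the gene) / total_runs, counting
    also the runs in which the class was never discovered. Top n_genes by
    frequency; ties broken by mean within-run rank, then gene id.
    """
    if not per_run_selections:
        raise ValueError("no runs contributed to this class")
    counts: dict = {}
    ranks: dict = {}
    for _run, genes in per_run_selections.items():
        for rank, g in enumerate(genes):
            counts[g] = counts.get(g, 0) + 1
            ranks.setdefault(g, []).append(rank)
    rows = [(g, 100.0 * c / total_runs, float(np.mean(ranks[g])))
            for g, c in counts.items()]
    rows.sort(key=lambda r: (-r[1], r[2], str(r[0])))
    top = rows[: params.n_genes]
    return GeneSignature(class_name,
                         [g for g, _f, _r in top],
                         [f for _g, f, _r in top],
                         sorted(per_run_selections, key=str))


def combine_signatures(a: GeneSignature, b: GeneSignature,
                       mode: str = "union") -> GeneSignature:
    """Set union ("union") or difference ("a_minus_b") of two signatures."""
    if not a.genes or not b.genes:
        raise ValueError("both signatures must be non-empty")
    freq_a = dict(zip(a.genes, a.frequencies or [np.nan] * len(a.genes)))
    freq_b = dict(zip(b.genes, b.frequencies or [np.nan] * len(b.genes)))
    if mode == "union":
        genes = list(a.genes) + [g for g in b.genes if g not in set(a.genes)]
        freqs = [max(filter(lambda v: v == v, [freq_a.get(g, np.nan),
                                               freq_b.get(g, np.nan)]), default=np.nan)
                 for g in genes]
        name = f"{a.class_name}+{b.class_name}"
    elif mode == "a_minus_b":
        genes = [g for g in a.genes if g not in set(b.genes)]
        freqs = [freq_a[g] for g in genes]
        name = f"{a.class_name}-{b.class_name}"
        if not genes:
            warnings.warn(f"signature {name} is empty")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GeneSignature(name, genes, freqs,
                         sorted(set(a.provenance) | set(b.provenance), key=str))
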