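"""Empirical random-gene null for signature model performance.

100 random 10-gene sets are drawn from the genes with more than
`min_total_reads` mapped reads across all samples, each is evaluated on
the same resampling plan as the focal model, and the empirical P of the
focal model is the fraction of random-set models with a strictly higher
median AUC (no continuity correction, so P may be exactly 0).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import CountMatrix
from .predict import ModelConfig, ResamplePlan, RunFeatureExtractor, evaluate_gene_sets
from .preprocess import filter_low_counts
from .synthdata import CohortBundle


@dataclass
class NullEnsemble:
    """The random gene sets and, once evaluated, their per-set median AUCs."""

    gene_sets: list                      # list of gene-id lists
    medians: np.ndarray | None = None
    set_size: int = 10
    min_total_reads: int = 5

    def to_dict(self) -> dict:
        return {"gene_sets": [list(s) for s in self.gene_sets],
                "medians": None if self.medians is None else list(map(float, self.medians)),
                "set_size": self.set_size, "min_total_reads": self.min_total_reads}


def sample_random_genesets(counts: CountMatrix, n_sets: int = 100, set_size: int = 10,
                           min_total_reads: int = 5, seed: int = 0) -> NullEnsemble:
    """Uniform without-replacement draws of gene sets from the filtered pool."""
    pool = filter_low_counts(counts, min_total_reads).gene_ids
    if len(pool) < set_size:
        raise ValueError(f"filtered pool ({len(pool)}) smaller than set size {set_size}")
    rng = np.random.default_rng(seed)
    sets = [list(rng.choice(pool, size=set_size, replace=False)) for _ in range(n_sets)]
    return NullEnsemble(sets, set_size=set_size, min_total_reads=min_total_reads)


def null_model_aucs(bundle: CohortBundle, ensemble: NullEnsemble, plan: ResamplePlan,
                    config: ModelConfig = None,
                    extractor: RunFeatureExtractor | None = None) -> NullEnsemble:
    """Evaluate each random set on the shared plan; fills per-set median AUCs."""
    gene_sets = {f"null_{i:03d}": s for i, s in enumerate(ensemble.gene_sets)}
    reports = evaluate_gene_sets(bundle, gene_sets, plan, config, extractor)
    ensemble.medians = np.array([reports[f"null_{i:03d}"].median_auc
                                 for i in range(len(ensemble.gene_sets))])
    return ensemble


def empirical_pvalue(model_median_auc: float, null_medians) -> float:
    """Fraction of null medians strictly greater than the model median."""
    nm = np.asarray(null_medians, dtype=float)
    if len(nm) == 0:
        raise ValueError("null ensemble is empty")
    return float(np.mean(nm > model_median_auc))
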