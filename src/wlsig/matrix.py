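"""Core count-matrix container for bulk RNA-seq gene-level counts.

The matrix is genes x samples (edgeR/DESeq2 orientation) with string
identifiers on both axes and non-negative integer values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample matrix with identifiers.

    Parameters
    ----------
    gene_ids : sequence of str
        Row identifiers, unique, order-preserving.
    sample_ids : sequence of str
        Column identifiers, unique, order-preserving.
    values : ndarray of shape (n_genes, n_samples)
        Read counts; coerced to int64.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("count matrix must be 2-D (genes x samples)")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            values = np.round(values).astype(np.int64)
        self.values = values.astype(np.int64, copy=False)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lengths")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.sample_ids) < 2:
            raise ValueError("count matrix needs at least 2 samples")

    # ---- constructors -------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        """Build from a genes x samples DataFrame."""
        return cls(frame.index.to_numpy(object),
                   frame.columns.to_numpy(object),
                   frame.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=pd.Index(self.sample_ids, name="sample_id"))

    # ---- views --------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_totals(self) -> np.ndarray:
        """Total reads per gene across all samples."""
        return self.values.sum(axis=1)

    def library_sizes(self) -> np.ndarray:
        """Total reads per sample."""
        return self.values.sum(axis=0)

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"gene id not in matrix: {exc.args[0]}") from None

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise KeyError(f"sample id not in matrix: {exc.args[0]}") from None

    def subset_genes(self, gene_ids) -> "CountMatrix":
        idx = self.gene_index(gene_ids)
        return CountMatrix(self.gene_ids[idx], self.sample_ids, self.values[idx])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = self.sample_index(sample_ids)
        return CountMatrix(self.gene_ids, self.sample_ids[idx], self.values[:, idx])
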