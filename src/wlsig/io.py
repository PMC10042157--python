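"""Readers/writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (genes x samples) or MatrixMarket with id sidecars;
gene sets as GMT; tabular metadata as TSV; structured results as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import CountMatrix


# ---- counts ----------------------------------------------------------
def read_counts_tsv(path) -> CountMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(frame)


def write_counts_tsv(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t")


def read_counts_mtx(path) -> CountMatrix:
    """Read MatrixMarket counts with `<stem>.genes.txt` / `<stem>.samples.txt` sidecars."""
    path = Path(path)
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    stem = path.with_suffix("")
    genes = stem.with_suffix(".genes.txt").read_text().split()
    samples = stem.with_suffix(".samples.txt").read_text().split()
    return CountMatrix(np.array(genes, object), np.array(samples, object), mat)


def write_counts_mtx(counts: CountMatrix, path) -> None:
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.values))
    stem = path.with_suffix("")
    stem.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.gene_ids)) + "\n")
    stem.with_suffix(".samples.txt").write_text("\n".join(map(str, counts.sample_ids)) + "\n")


# ---- tables ----------------------------------------------------------
def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t")


# ---- GMT gene sets ---------------------------------------------------
def read_gmt(path) -> dict[str, dict]:
    """Parse a GMT file into {term_id: {"name": description, "genes": set}}."""
    terms: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        term_id, name, genes = parts[0], parts[1], parts[2:]
        terms[term_id] = {"name": name, "genes": set(genes)}
    return terms


def write_gmt(terms: dict[str, dict], path) -> None:
    lines = []
    for term_id, rec in terms.items():
        genes = "\t".join(sorted(map(str, rec["genes"])))
        lines.append(f"{term_id}\t{rec.get('name', term_id)}\t{genes}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---- JSON ------------------------------------------------------------
class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, set):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
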