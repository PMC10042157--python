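"""Over-representation analysis and enrichment-map construction.

Terms (flat gene sets, GMT-style) are tested against the DEG set by the
upper-tail hypergeometric test, BH-corrected, and the significant terms
are arranged into an enrichment map: near-duplicate terms (Jaccard >=
0.7) are collapsed onto the best-P representative, remaining terms are
joined by edges at Jaccard >= 0.2, and the connected components of that
graph become the candidate pathway classes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class TermAnnotation:
    """term_id -> (name, gene set) plus the background universe."""

    terms: dict
    universe: set

    def __post_init__(self) -> None:
        for tid, rec in self.terms.items():
            if not rec["genes"]:
                raise ValueError(f"term {tid!r} has no genes")
            extra = set(rec["genes"]) - self.universe
            if extra:
                raise ValueError(f"term {tid!r} has genes outside the universe")

    @classmethod
    def from_terms(cls, terms: dict, universe) -> "TermAnnotation":
        """Restrict terms to the universe, dropping those left with < 1 gene."""
        universe = set(universe)
        kept = {}
        for tid, rec in terms.items():
            genes = set(rec["genes"]) & universe
            if genes:
                kept[tid] = {"name": rec.get("name", tid), "genes": genes}
        return cls(kept, universe)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for k successes.

    k of the n selected genes fall in a term of size K out of a universe
    of N genes. Computed in log space via scipy's hypergeometric survival
    function.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError("inconsistent hypergeometric counts")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("P-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def jaccard(a, b) -> float:
    """|a n b| / |a u b| for two non-empty gene sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Jaccard similarity needs non-empty sets")
    return len(a & b) / len(a | b)


def enrich_terms(
    selected,
    annotation: TermAnnotation,
    p_cut: float = 0.05,
    q_cut: float = 0.2,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every term overlapping the selection.

    A term is significant when P < p_cut and q < q_cut and q < fdr_cut
    (the latter two both apply; each is configurable). Selected genes
    outside the universe are dropped with a logged count.
    """
    selected = set(selected)
    outside = selected - annotation.universe
    if outside:
        log.info("dropping %d selected genes outside the universe", len(outside))
        selected -= outside
    N = len(annotation.universe)
    n = len(selected)
    rows = []
    for tid, rec in annotation.terms.items():
        k = len(rec["genes"] & selected)
        if k < 1:
            continue
        K = len(rec["genes"])
        rows.append((tid, rec["name"], k, K, n, N, hypergeom_test(k, K, n, N)))
    if not rows:
        log.warning("no term overlaps the selected gene set")
        return pd.DataFrame(
            columns=["term_name", "k", "K", "n", "N", "pvalue", "qvalue",
                     "significant"]).rename_axis("term_id")
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "pvalue"]
    ).set_index("term_id")
    table["qvalue"] = bh_adjust(table["pvalue"].to_numpy())
    table["significant"] = ((table["pvalue"] < p_cut)
                            & (table["qvalue"] < q_cut)
                            & (table["qvalue"] < fdr_cut))
    return table


@dataclass
class EnrichmentMap:
    """Graph over retained enriched terms with labelled components."""

    graph: nx.Graph
    similarity: pd.DataFrame
    components: list            # list of lists of term ids
    dropped_redundant: list = field(default_factory=list)

    def component_gene_union(self, annotation: TermAnnotation, idx: int) -> set:
        genes: set = set()
        for tid in self.components[idx]:
            genes |= annotation.terms[tid]["genes"]
        return genes

    def edge_list(self) -> pd.DataFrame:
        """Edges as a (source, target, similarity) table for TSV export."""
        rows = [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "similarity"])

    def components_dict(self) -> dict:
        """Components as {component_<i>: [term ids]} for JSON export."""
        return {f"component_{i}": list(c) for i, c in enumerate(self.components)}


def build_map(
    table: pd.DataFrame,
    annotation: TermAnnotation,
    redundancy_cut: float = 0.7,
    edge_cut: float = 0.2,
) -> EnrichmentMap:
    """Enrichment map over the significant terms of an enrichment table.

    1) redundancy collapse: among pairs with Jaccard >= redundancy_cut,
       iteratively drop the larger-P term (ties by term_id);
    2) connect retained terms with Jaccard >= edge_cut;
    3) components = connected components, singletons included.
    """
    sig = table[table["significant"]] if "significant" in table else table
    term_ids = sorted(sig.index)
    sim = pd.DataFrame(np.eye(len(term_ids)), index=term_ids, columns=term_ids)
    for i, a in enumerate(term_ids):
        for b in term_ids[i + 1:]:
            s = jaccard(annotation.terms[a]["genes"], annotation.terms[b]["genes"])
            sim.loc[a, b] = sim.loc[b, a] = s

    # iterative redundancy collapse, deterministic order
    retained = list(term_ids)
    dropped = []
    pval = sig["pvalue"]
    while True:
        worst = None
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                if sim.loc[a, b] >= redundancy_cut:
                    # drop the larger-P term; ties broken by term_id
                    loser = b if (pval[b], str(b)) > (pval[a], str(a)) else a
                    if worst is None or (pval[loser], str(loser)) > worst[0]:
                        worst = ((pval[loser], str(loser)), loser)
        if worst is None:
            break
        retained.remove(worst[1])
        dropped.append(worst[1])

    g = nx.Graph()
    g.add_nodes_from(retained)
    for i, a in enumerate(retained):
        for b in retained[i + 1:]:
            if sim.loc[a, b] >= edge_cut:
                g.add_edge(a, b, weight=float(sim.loc[a, b]))
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (min(pval[t] for t in c), c[0]))
    return EnrichmentMap(g, sim, components, dropped)
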