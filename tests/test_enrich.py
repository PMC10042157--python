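"""Enrichment statistics and map construction against exact oracles."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from wlsig.enrich import (TermAnnotation, bh_adjust, build_map, enrich_terms,
                          hypergeom_test, jaccard)


# ---- hypergeometric vs exact rational enumeration --------------------
def _hyper_exact(k, K, n, N) -> float:
    """Upper-tail probability by exact rational enumeration."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


def test_hypergeom_trivial_and_worked_cases():
    assert hypergeom_test(0, 5, 5, 20) == 1.0
    assert abs(hypergeom_test(5, 5, 5, 10) - 1 / 252) < 1e-15
    assert abs(hypergeom_test(3, 5, 6, 20) - _hyper_exact(3, 5, 6, 20)) < 1e-12


def test_hypergeom_matches_enumeration_exhaustively():
    for N in (10, 17, 30):
        for K in (3, N // 2):
            for n in (2, N // 3, K):
                for k in range(0, min(K, n) + 1):
                    assert abs(hypergeom_test(k, K, n, N)
                               - _hyper_exact(k, K, n, N)) < 1e-12


def test_hypergeom_domain_errors():
    with pytest.raises(ValueError):
        hypergeom_test(6, 5, 6, 20)
    with pytest.raises(ValueError):
        hypergeom_test(1, 25, 6, 20)


# ---- Benjamini-Hochberg ----------------------------------------------
def _bh_oracle(p):
    """Straight transcription of the step-up formula."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def test_bh_known_and_random_vectors(rng):
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    for _ in range(10):
        p = rng.random(rng.integers(1, 40))
        q = bh_adjust(p)
        assert np.allclose(q, _bh_oracle(p), atol=1e-12)
        # monotone in the input order of P
        srt = np.argsort(p)
        assert (np.diff(q[srt]) >= -1e-12).all()
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---- Jaccard ---------------------------------------------------------
def test_jaccard_cases():
    assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
    assert jaccard({"a"}, {"b"}) == 0.0
    assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
    with pytest.raises(ValueError):
        jaccard(set(), {"a"})


# ---- enrichment table ------------------------------------------------
def _toy_annotation():
    universe = {f"g{i}" for i in range(40)}
    terms = {
        "T_mod": {"name": "module process", "genes": {f"g{i}" for i in range(10)}},
        "T_half": {"name": "half process", "genes": {f"g{i}" for i in range(5, 15)}},
        "T_bg": {"name": "background process", "genes": {f"g{i}" for i in range(20, 35)}},
    }
    return TermAnnotation(terms, universe)


def test_enrich_planted_term_has_minimum_p():
    annot = _toy_annotation()
    table = enrich_terms({f"g{i}" for i in range(10)}, annot)
    assert table["pvalue"].idxmin() == "T_mod"
    assert table.loc["T_mod", "significant"]
    assert "T_bg" not in table.index          # disjoint -> untested
    # selected = universe -> P = 1 everywhere
    full = enrich_terms(annot.universe, annot)
    assert (full["pvalue"] == 1.0).all()


def test_enrich_empty_selection_gives_empty_table():
    table = enrich_terms(set(), _toy_annotation())
    assert table.empty


def test_annotation_validation():
    with pytest.raises(ValueError, match="outside the universe"):
        TermAnnotation({"T": {"name": "t", "genes": {"zzz"}}}, {"a"})
    restricted = TermAnnotation.from_terms(
        {"T": {"name": "t", "genes": {"a", "zzz"}}}, {"a", "b"})
    assert restricted.terms["T"]["genes"] == {"a"}


# ---- enrichment map --------------------------------------------------
def _union_find_components(term_ids, sim, cut):
    parent = {t: t for t in term_ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, a in enumerate(term_ids):
        for b in term_ids[i + 1:]:
            if sim[(a, b)] >= cut:
                parent[find(b)] = find(a)
    groups = {}
    for t in term_ids:
        groups.setdefault(find(t), set()).add(t)
    return {frozenset(g) for g in groups.values()}


def test_redundancy_collapse_keeps_smaller_p():
    universe = {f"g{i}" for i in range(30)}
    terms = {"A": {"name": "a", "genes": {f"g{i}" for i in range(10)}},
             "B": {"name": "b", "genes": {f"g{i}" for i in range(1, 10)}}}
    annot = TermAnnotation(terms, universe)
    table = enrich_terms({f"g{i}" for i in range(10)}, annot)
    assert table.loc["A", "pvalue"] < table.loc["B", "pvalue"]
    emap = build_map(table, annot)
    assert list(emap.graph.nodes) == ["A"]
    assert emap.dropped_redundant == ["B"]


def test_components_match_union_find_oracle(rng):
    universe = {f"g{i}" for i in range(120)}
    terms = {}
    for t in range(8):
        size = int(rng.integers(5, 25))
        genes = set(rng.choice(sorted(universe), size=size, replace=False).tolist())
        terms[f"T{t}"] = {"name": f"term {t}", "genes": genes}
    annot = TermAnnotation(terms, universe)
    selected = set(rng.choice(sorted(universe), size=40, replace=False).tolist())
    table = enrich_terms(selected, annot, p_cut=1.1, q_cut=1.1, fdr_cut=1.1)
    emap = build_map(table, annot, redundancy_cut=1.01, edge_cut=0.2)
    sim = {(a, b): jaccard(terms[a]["genes"], terms[b]["genes"])
           for a in table.index for b in table.index if a != b}
    expected = _union_find_components(sorted(table.index), sim, 0.2)
    assert {frozenset(c) for c in emap.components} == expected
    # component gene union equals the union of member terms' genes
    for idx, comp in enumerate(emap.components):
        union = set().union(*(terms[t]["genes"] for t in comp))
        assert emap.component_gene_union(annot, idx) == union
    # exports are consistent with the graph
    edges = emap.edge_list()
    assert len(edges) == emap.graph.number_of_edges()
    assert (edges["similarity"] >= 0.2).all()
    assert sorted(map(sorted, emap.components_dict().values())) == \
        sorted(map(sorted, emap.components))


def test_three_terms_pairwise_similar_form_one_component():
    universe = {f"g{i}" for i in range(40)}
    terms = {"A": {"name": "a", "genes": {"g0", "g1", "g2", "g3"}},
             "B": {"name": "b", "genes": {"g2", "g3", "g4", "g5"}},
             "C": {"name": "c", "genes": {"g4", "g5", "g0", "g1"}}}
    annot = TermAnnotation(terms, universe)
    table = enrich_terms({f"g{i}" for i in range(6)}, annot,
                         p_cut=1.1, q_cut=1.1, fdr_cut=1.1)
    emap = build_map(table, annot)
    assert len(emap.components) == 1 and len(emap.components[0]) == 3
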