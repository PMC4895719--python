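"""Alignment kernel, significance proxy, and the clustering layers."""

import numpy as np
import pytest
from Bio.Seq import Seq

from oracles import smith_waterman_oracle, transitive_closure_oracle
from subtracta.homology import (HomologyHit, MCLConvergenceError, SimilarityGraph,
                                aa_params, align_pair, all_vs_all,
                                classify_orthologs, evalue_from_score,
                                mcl_cluster, nt_params, silix_cluster,
                                species_specific)
from subtracta.synthgen import mutate_to_ks, random_cds


def _protein(n_codons, rng):
    return str(Seq(random_cds(n_codons, rng)).translate())


# ---------------------------------------------------------------------------
# align_pair

def test_self_alignment_full_identity(rng):
    s = _protein(120, rng)
    hit = align_pair(s, s, aa_params())
    assert hit.identity == 100.0
    assert hit.qcov == 1.0 and hit.scov == 1.0


def test_nt_raw_score_closed_form():
    hit = align_pair("ACGT", "ACGT", nt_params(evalue_max=None))
    assert hit.raw_score == 4.0


def test_mismatched_alphabet_names_offending_characters():
    with pytest.raises(ValueError, match="J"):
        align_pair("ACGJ", "ACGT", nt_params())


def test_unrelated_sequences_are_no_hit_and_oracle_agrees(rng):
    """Two nt sequences sharing no 4-mer: no hit at E<=1e-5, and a
    brute-force DP oracle confirms the best local score is below the
    score the E threshold would require."""
    a = "AC" * 20  # 4-mers: ACAC/CACA only
    b = "GT" * 20
    params = nt_params()
    assert align_pair(a, b, params) is None
    best = smith_waterman_oracle(a, b)
    assert evalue_from_score(best, len(a), len(b), params) > 1e-5


def test_evalue_monotone_decreasing_in_score():
    p = nt_params()
    es = [evalue_from_score(s, 100, 1000, p) for s in (10, 20, 40)]
    assert es[0] > es[1] > es[2]


# ---------------------------------------------------------------------------
# all_vs_all

def test_three_identical_sequences_complete_graph(rng):
    s = _protein(150, rng)
    sg = all_vs_all({"a": s, "b": s, "c": s})
    assert set(sg.graph.edges) == {("a", "b"), ("a", "c"), ("b", "c")} or \
        sg.graph.number_of_edges() == 3


def test_empty_input_empty_graph():
    sg = all_vs_all({})
    assert sg.graph.number_of_nodes() == 0 and not sg.hits


def test_duplicate_ids_rejected(rng):
    s = _protein(50, rng)
    with pytest.raises(ValueError, match="duplicate"):
        all_vs_all([("x", s), ("x", s)])


def test_planted_families_stay_in_separate_components(rng):
    import networkx as nx
    fam1 = random_cds(150, rng)
    fam2 = random_cds(150, rng)
    genes = {}
    for i in range(3):
        genes[f"f1_{i}"] = str(Seq(mutate_to_ks(fam1, 0.2, rng).seq).translate())
        genes[f"f2_{i}"] = str(Seq(mutate_to_ks(fam2, 0.2, rng).seq).translate())
    sg = all_vs_all(genes)
    comps = [frozenset(c) for c in nx.connected_components(sg.graph)]
    assert frozenset({"f1_0", "f1_1", "f1_2"}) in comps
    assert frozenset({"f2_0", "f2_1", "f2_2"}) in comps


# ---------------------------------------------------------------------------
# SiLiX-style clustering

def _hit(q, s, ident=90.0, cov=0.9):
    return HomologyHit(qid=q, sid=s, identity=ident, length=100,
                       qcov=cov, scov=cov, raw_score=100, bit_score=50,
                       evalue=1e-20)


def test_silix_identity_threshold_is_strict():
    ids = ["A", "B"]
    clusters = silix_cluster(ids, [_hit("A", "B", ident=29.9)])
    assert clusters == [frozenset({"A"}), frozenset({"B"})]


def test_silix_overlap_uses_min_of_coverages():
    h = _hit("A", "B")
    h.qcov, h.scov = 0.9, 0.4  # min coverage below the 0.5 default
    assert silix_cluster(["A", "B"], [h]) == [frozenset({"A"}), frozenset({"B"})]


def test_silix_transitive_chain_links_all():
    hits = [_hit("A", "B"), _hit("B", "C")]
    assert silix_cluster(["A", "B", "C"], hits) == [frozenset({"A", "B", "C"})]


def test_silix_equals_bruteforce_closure_on_small_graphs(rng):
    for _ in range(100):
        n = int(rng.integers(2, 9))
        ids = [f"n{i}" for i in range(n)]
        hits, passing = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    ident = float(rng.uniform(0, 100))
                    cov = float(rng.uniform(0, 1))
                    hits.append(_hit(ids[i], ids[j], ident=ident, cov=cov))
                    if ident >= 30 and cov >= 0.5:
                        passing.append((ids[i], ids[j]))
        assert silix_cluster(ids, hits) == \
            transitive_closure_oracle(ids, passing)


def test_raising_thresholds_only_refines(rng):
    ids = [f"n{i}" for i in range(10)]
    hits = []
    for i in range(10):
        for j in range(i + 1, 10):
            if rng.random() < 0.5:
                hits.append(_hit(ids[i], ids[j],
                                 ident=float(rng.uniform(20, 100)),
                                 cov=float(rng.uniform(0.3, 1.0))))
    loose = silix_cluster(ids, hits, min_identity=30, min_overlap=0.5)
    strict = silix_cluster(ids, hits, min_identity=60, min_overlap=0.7)
    parent = {}
    for c in loose:
        for g in c:
            parent[g] = c
    for c in strict:
        assert len({parent[g] for g in c}) == 1  # each strict cluster nested


# ---------------------------------------------------------------------------
# MCL

def _graph(edges):
    g = SimilarityGraph()
    import networkx as nx
    gg = nx.Graph()
    for a, b, w in edges:
        gg.add_edge(a, b, weight=w)
    g.graph = gg
    return g


def test_mcl_two_cliques_two_clusters():
    edges = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
    assert mcl_cluster(_graph(edges)) == [frozenset("abc"), frozenset("xyz")]


def test_mcl_single_node_singleton():
    g = SimilarityGraph(["solo"])
    assert mcl_cluster(g) == [frozenset({"solo"})]


def test_mcl_barbell_splits_at_weak_bridge():
    edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
             ("x", "y", 1.0), ("y", "z", 1.0), ("x", "z", 1.0),
             ("c", "x", 0.1)]
    assert mcl_cluster(_graph(edges), inflation=1.5) == \
        [frozenset("abc"), frozenset("xyz")]


def test_mcl_requires_inflation_above_one():
    with pytest.raises(ValueError):
        mcl_cluster(SimilarityGraph(["a"]), inflation=1.0)


def test_mcl_never_merges_disconnected_components(rng):
    import networkx as nx
    for _ in range(60):
        n = int(rng.integers(4, 12))
        g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(0, 1 << 30)))
        for _, _, d in g.edges(data=True):
            d["weight"] = float(rng.uniform(0.1, 1.0))
        comps = list(nx.connected_components(g))
        comp_of = {}
        for ci, comp in enumerate(comps):
            for node in comp:
                comp_of[node] = ci
        for cluster in mcl_cluster(g):
            assert len({comp_of[x] for x in cluster}) == 1


def test_mcl_partition_covers_all_nodes(rng):
    import networkx as nx
    g = nx.gnp_random_graph(15, 0.25, seed=5)
    for _, _, d in g.edges(data=True):
        d["weight"] = 1.0
    clusters = mcl_cluster(g)
    all_nodes = [x for c in clusters for x in c]
    assert sorted(all_nodes) == sorted(g.nodes)
    assert len(all_nodes) == len(set(all_nodes))


# ---------------------------------------------------------------------------
# Orthology classes

@pytest.mark.parametrize("na,nb,label", [
    (1, 1, "one to one"), (1, 2, "one to two"), (1, 5, "one to many"),
    (2, 1, "two to one"), (2, 2, "two to two"), (2, 3, "two to many"),
    (3, 1, "many to one"), (4, 2, "many to two"), (3, 3, "many to many"),
])
def test_nine_orthology_classes(na, nb, label):
    cluster = frozenset([f"a{i}" for i in range(na)]
                        + [f"b{i}" for i in range(nb)])
    species_of = {g: ("A" if g.startswith("a") else "B") for g in cluster}
    groups, single = classify_orthologs([cluster], species_of)
    assert len(groups) == 1 and not single
    assert groups[0].class_label == label


def test_single_species_cluster_routed_to_specific():
    cluster = frozenset({"a1", "a2", "a3"})
    groups, single = classify_orthologs([cluster], {g: "A" for g in cluster})
    assert not groups and single == [cluster]


def test_three_species_input_rejected():
    with pytest.raises(ValueError, match="pairwise"):
        classify_orthologs([frozenset({"a", "b", "c"})],
                           {"a": "A", "b": "B", "c": "C"})


# ---------------------------------------------------------------------------
# Species-specific genes

def test_species_specific_planted_recovery(rng):
    base = {f"og{i}": random_cds(120, rng) for i in range(4)}
    genes_a = {f"A_{k}": v for k, v in base.items()}
    genes_b = {f"B_{k}": str(Seq(mutate_to_ks(v, 0.2, rng).seq)) for k, v in
               base.items()}
    prot_a = {k: str(Seq(v).translate()) for k, v in genes_a.items()}
    prot_b = {k: str(Seq(v).translate()) for k, v in genes_b.items()}
    # planted: one in-paralogue of og0 in A, three single-copy A-specific
    prot_a["A_par"] = prot_a["A_og0"]
    for i in range(3):
        prot_a[f"A_spec{i}"] = str(Seq(random_cds(120, rng)).translate())
    from subtracta.homology import OrthologGroup
    groups = [OrthologGroup(f"OG{i}", {"A": frozenset({f"A_og{i}"}),
                                       "B": frozenset({f"B_og{i}"})},
                            "one to one") for i in range(4)]
    res_a, res_b = species_specific(prot_a, prot_b, groups)
    assert set(res_a.in_paralogues) == {"A_par"}
    assert res_a.in_paralogues["A_par"] == "OG0"
    assert res_a.single_copy == {"A_spec0", "A_spec1", "A_spec2"}
    assert not res_b.single_copy and not res_b.in_paralogues
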