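"""OBO loading and once-per-product DAG propagation counting."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ventannot.errors import FormatError
from ventannot.ontology import (NAMESPACES, OntologyDag, annotation_summary,
                                load_obo, propagate_counts)
from ventannot.synthetic import simulate_ontology

MINIMAL_OBO = """format-version: 1.2

[Term]
id: GO:0008150
name: biological process
namespace: biological_process

[Term]
id: GO:0003674
name: molecular function
namespace: molecular_function

[Term]
id: GO:0005575
name: cellular component
namespace: cellular_component
"""


def _assign(pairs):
    return pd.DataFrame(pairs, columns=["product_id", "term_id"])


def _brute_counts(assignments, dag, depth):
    """Independent oracle: per-product ancestor-set union by repeated
    edge relaxation, then category membership."""
    edges = list(dag.graph.edges())
    categories = set()
    for root in dag.roots.values():
        frontier = {root}
        for _ in range(depth):
            frontier = {c for c, p in edges if p in frontier}
        categories |= frontier
    counts = {c: 0 for c in categories}
    for _, grp in assignments.groupby("product_id"):
        closure = set(grp["term_id"])
        changed = True
        while changed:
            changed = False
            for child, parent in edges:
                if child in closure and parent not in closure:
                    closure.add(parent)
                    changed = True
        for cat in closure & categories:
            counts[cat] += 1
    return counts


def test_minimal_three_root_file(tmp_path):
    path = tmp_path / "min.obo"
    path.write_text(MINIMAL_OBO)
    dag = load_obo(path)
    assert len(dag) == 3
    assert dag.graph.number_of_edges() == 0
    assert set(dag.roots) == set(NAMESPACES)


def test_obo_roundtrip(tmp_path, dag):
    path = tmp_path / "synthetic.obo"
    dag.to_obo(path)
    back = load_obo(path)
    assert set(back.terms) == set(dag.terms)
    assert set(back.graph.edges()) == set(dag.graph.edges())


def test_loaded_ancestors_match_bruteforce(tmp_path):
    dag = simulate_ontology(n_terms=500, max_parents=3, seed=12)
    path = tmp_path / "big.obo"
    dag.to_obo(path)
    loaded = load_obo(path)
    edges = list(loaded.graph.edges())
    rng = np.random.default_rng(1)
    terms = sorted(loaded.terms)
    for idx in rng.choice(len(terms), size=15, replace=False):
        term = terms[int(idx)]
        closure = {term}
        changed = True
        while changed:
            changed = False
            for child, parent in edges:
                if child in closure and parent not in closure:
                    closure.add(parent)
                    changed = True
        assert loaded.ancestors(term) == closure


def test_dangling_is_a_reference_is_error(tmp_path):
    path = tmp_path / "bad.obo"
    path.write_text(MINIMAL_OBO + "\n[Term]\nid: GO:0000001\nname: orphan\n"
                    "namespace: biological_process\nis_a: GO:9999999\n")
    with pytest.raises(FormatError, match="GO:9999999"):
        load_obo(path)


def test_cycle_is_error():
    g = nx.DiGraph()
    for tid, ns in [("GO:0008150", "biological_process"),
                    ("GO:0003674", "molecular_function"),
                    ("GO:0005575", "cellular_component")]:
        g.add_node(tid, name=ns, namespace=ns)
    for tid in ("GO:0000001", "GO:0000002"):
        g.add_node(tid, name=tid, namespace="biological_process")
    g.add_edge("GO:0000001", "GO:0000002")
    g.add_edge("GO:0000002", "GO:0000001")
    with pytest.raises(FormatError, match="cycle"):
        OntologyDag(graph=g)


@pytest.fixture(scope="module")
def toy():
    """bp root -> {cat1, cat2}; cat1 -> {leafA, leafB}; cat2 -> leafC."""
    g = nx.DiGraph()
    nodes = {
        "GO:0008150": "biological_process",
        "GO:0003674": "molecular_function",
        "GO:0005575": "cellular_component",
    }
    for tid, ns in nodes.items():
        g.add_node(tid, name=ns, namespace=ns)
    for tid in ("cat1", "cat2", "leafA", "leafB", "leafC"):
        g.add_node(tid, name=tid, namespace="biological_process")
    g.add_edge("cat1", "GO:0008150")
    g.add_edge("cat2", "GO:0008150")
    g.add_edge("leafA", "cat1")
    g.add_edge("leafB", "cat1")
    g.add_edge("leafC", "cat2")
    return OntologyDag(graph=g)


class TestPropagation:
    def test_single_leaf_counts_once(self, toy):
        rep = propagate_counts(_assign([("p1", "leafA")]), toy)
        counts = rep.counts()
        assert counts["cat1"] == 1
        assert all(v == 0 for k, v in counts.items() if k != "cat1")

    def test_two_leaves_sharing_category_count_once(self, toy):
        rep = propagate_counts(
            _assign([("p1", "leafA"), ("p1", "leafB")]), toy)
        assert rep.counts()["cat1"] == 1

    def test_product_in_two_categories_counts_in_both(self, toy):
        rep = propagate_counts(
            _assign([("p1", "leafA"), ("p1", "leafC")]), toy)
        counts = rep.counts()
        assert counts["cat1"] == 1 and counts["cat2"] == 1

    def test_root_only_product_reported(self, toy):
        rep = propagate_counts(_assign([("p1", "GO:0008150")]), toy)
        assert rep.root_only == {"p1"}
        assert all(v == 0 for v in rep.counts().values())

    def test_unknown_term_skipped_with_warning(self, toy):
        with pytest.warns(UserWarning, match="unknown"):
            rep = propagate_counts(
                _assign([("p1", "leafA"), ("p2", "GO:404")]), toy)
        assert len(rep.skipped) == 1
        assert rep.counts()["cat1"] == 1

    def test_percentages_sum_to_100_per_namespace(self, dag):
        rng = np.random.default_rng(5)
        leaves = sorted(simulate_ontology(120, seed=3).leaves())
        pairs = [(f"p{i}", leaves[int(rng.integers(len(leaves)))])
                 for i in range(80)]
        rep = propagate_counts(_assign(pairs), dag)
        for ns, grp in rep.table.groupby("namespace"):
            if grp["count"].sum() > 0:
                assert grp["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_counts_match_bruteforce_on_random_dag(self):
        dag = simulate_ontology(n_terms=200, max_parents=3, seed=21)
        leaves = sorted(dag.leaves())
        rng = np.random.default_rng(2)
        pairs = []
        for i in range(50):
            for t in rng.choice(len(leaves), size=int(rng.integers(1, 4)),
                                replace=False):
                pairs.append((f"p{i:02d}", leaves[int(t)]))
        assignments = _assign(pairs)
        rep = propagate_counts(assignments, dag)
        assert rep.counts() == _brute_counts(assignments, dag, 1)

    def test_edge_addition_never_decreases_counts(self):
        dag = simulate_ontology(n_terms=60, seed=8)
        leaves = sorted(dag.leaves())
        rng = np.random.default_rng(9)
        pairs = [(f"p{i}", leaves[int(rng.integers(len(leaves)))])
                 for i in range(30)]
        before = propagate_counts(_assign(pairs), dag).counts()
        # add an is_a edge from a leaf to another same-namespace term
        for leaf in leaves:
            ns = dag.namespace_of(leaf)
            targets = [t for t in dag.terms
                       if dag.namespace_of(t) == ns
                       and t != leaf and t not in dag.ancestors(leaf)
                       and leaf not in dag.ancestors(t)]
            if targets:
                g2 = dag.graph.copy()
                g2.add_edge(leaf, sorted(targets)[0])
                dag2 = OntologyDag(graph=g2)
                after = propagate_counts(_assign(pairs), dag2).counts()
                assert all(after[c] >= v for c, v in before.items())
                break


class TestAnnotationSummary:
    def _tables(self, domain_ids, go_ids):
        return (pd.DataFrame({"product_id": domain_ids}),
                pd.DataFrame({"product_id": go_ids}))

    def test_empty_tables_are_all_zero(self):
        interpro, go = self._tables([], [])
        assert annotation_summary([], interpro, go) == {
            "products": 0, "with_domain": 0, "with_go": 0}

    def test_constructed_overlap(self):
        interpro, go = self._tables(["a", "b"], ["b", "c"])
        out = annotation_summary(["a", "b", "c", "d"], interpro, go)
        assert out == {"products": 4, "with_domain": 2, "with_go": 2}

    def test_go_only_product(self):
        interpro, go = self._tables([], ["a"])
        out = annotation_summary(["a"], interpro, go)
        assert out["with_go"] == 1 and out["with_domain"] == 0
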