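"""Gene Ontology handling: a multi-root is_a DAG and propagation
counting.

Counting follows the true-path rule with once-per-product
deduplication: a product annotated to any number of descendant terms of
a reporting category contributes exactly 1 to that category. Reporting
categories default to the direct children of the three namespace roots.
Per-namespace percentages use the sum of that namespace's category
counts as denominator, so a product hitting k categories contributes k
to it.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import FormatError, InputError

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class OntologyDag:
    """Directed acyclic term graph; edges point child -> parent (is_a).

    Exactly one root per namespace; every term reaches the root of its
    own namespace.
    """

    graph: nx.DiGraph
    terms: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (name, namespace)
    roots: dict[str, str] = field(default_factory=dict)  # namespace -> id

    def __post_init__(self):
        if not self.terms:
            self.terms = {t: (d.get("name", t), d.get("namespace", ""))
                          for t, d in self.graph.nodes(data=True)}
        if not self.roots:
            self.roots = {self.terms[t][1]: t for t in self.graph
                          if self.graph.out_degree(t) == 0}
        self.validate()

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise FormatError(f"ontology contains a cycle: {cycle}")
        if set(self.roots) != set(NAMESPACES):
            raise FormatError(
                f"expected one root per namespace {NAMESPACES}, "
                f"found roots for {sorted(self.roots)}")
        root_ids = set(self.roots.values())
        for term in self.graph:
            if term in root_ids:
                continue
            reach = nx.descendants(self.graph, term) & root_ids
            if len(reach) != 1:
                raise FormatError(
                    f"term {term} reaches {len(reach)} namespace roots")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace_of(self, term: str) -> str:
        return self.terms[term][1]

    def name_of(self, term: str) -> str:
        return self.terms[term][0]

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """All terms reachable by is_a paths (the true-path closure)."""
        anc = nx.descendants(self.graph, term)
        if include_self:
            anc = anc | {term}
        return anc

    def terms_at_depth(self, depth: int) -> set[str]:
        """Terms whose shortest is_a path to their namespace root has the
        given length (depth 1 = direct children of a root)."""
        out: set[str] = set()
        rev = self.graph.reverse(copy=False)
        for root in self.roots.values():
            dists = nx.single_source_shortest_path_length(rev, root)
            out |= {t for t, d in dists.items() if d == depth}
        return out

    def leaves(self) -> set[str]:
        return {t for t in self.graph if self.graph.in_degree(t) == 0} \
            - set(self.roots.values())

    def to_obo(self, path) -> None:
        """Write the DAG as a minimal OBO v1.2 subset (id, name,
        namespace, is_a)."""
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\n")
            for term in sorted(self.terms):
                name, ns = self.terms[term]
                fh.write(f"\n[Term]\nid: {term}\nname: {name}\n"
                         f"namespace: {ns}\n")
                for parent in sorted(self.graph.successors(term)):
                    fh.write(f"is_a: {parent} ! {self.name_of(parent)}\n")


def load_obo(path) -> OntologyDag:
    """Load an OBO v1.2 subset into an :class:`OntologyDag`.

    Obsolete terms are dropped (with a warning when present); an is_a
    reference to an id with no [Term] stanza is a format error; cycles
    are format errors listing the offending edges.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=False)
    obsolete = [t for t, d in multi.nodes(data=True)
                if d.get("is_obsolete") == "true"]
    if obsolete:
        warnings.warn(f"dropping {len(obsolete)} obsolete terms",
                      stacklevel=2)
        multi.remove_nodes_from(obsolete)
    graph = nx.DiGraph()
    for term, data in multi.nodes(data=True):
        graph.add_node(term, **{k: data[k] for k in ("name", "namespace")
                                if k in data})
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    dangling = [t for t in graph if "name" not in graph.nodes[t]]
    if dangling:
        raise FormatError(
            f"is_a references to unknown term ids: {sorted(dangling)}")
    return OntologyDag(graph=graph)


@dataclass
class PropagationReport:
    table: pd.DataFrame  # namespace, term_id, name, count, percent
    n_products: int
    root_only: set[str] = field(default_factory=set)
    skipped: pd.DataFrame = None  # product_id, term_id of unknown terms

    def counts(self) -> dict[str, int]:
        return dict(zip(self.table["term_id"], self.table["count"]))


def propagate_counts(assignments: pd.DataFrame, dag: OntologyDag,
                     report_depth: int = 1) -> PropagationReport:
    """Count products per reporting category after DAG propagation.

    ``assignments`` has columns (product_id, term_id). Each product
    contributes at most 1 to each category regardless of how many of its
    terms descend from it. Assignments to unknown terms are skipped and
    reported. Products whose only propagated categories are the roots
    themselves appear in ``root_only``.
    """
    if report_depth < 1:
        raise InputError(f"report_depth must be >= 1, got {report_depth}")
    categories = dag.terms_at_depth(report_depth)
    known = assignments[assignments["term_id"].isin(dag.terms)]
    skipped = assignments[~assignments["term_id"].isin(dag.terms)]
    if len(skipped):
        warnings.warn(f"skipping {len(skipped)} assignments to unknown "
                      "terms", stacklevel=2)

    counts: dict[str, int] = {c: 0 for c in categories}
    root_only: set[str] = set()
    products = known.groupby("product_id", sort=True)["term_id"]
    for product, terms in products:
        closure: set[str] = set()
        for term in set(terms):
            closure |= dag.ancestors(term)
        hit = closure & categories
        for cat in hit:
            counts[cat] += 1
        if not hit:
            root_only.add(product)

    rows = []
    for ns in NAMESPACES:
        ns_cats = sorted(c for c in categories if dag.namespace_of(c) == ns)
        total = sum(counts[c] for c in ns_cats)
        for c in ns_cats:
            pct = 100.0 * counts[c] / total if total else float("nan")
            rows.append((ns, c, dag.name_of(c), counts[c], pct))
    table = pd.DataFrame(rows, columns=["namespace", "term_id", "name",
                                        "count", "percent"])
    return PropagationReport(table=table,
                             n_products=known["product_id"].nunique(),
                             root_only=root_only,
                             skipped=skipped.reset_index(drop=True))


def annotation_summary(product_ids: Iterable[str],
                       interpro: pd.DataFrame,
                       go: pd.DataFrame) -> dict[str, int]:
    """Accounting over annotation tables keyed by product id.

    Returns counts of products with a protein match (= any product id
    given), with a conserved-domain annotation, and with GO terms.
    """
    products = set(product_ids)
    with_domain = set(interpro["product_id"]) & products if len(interpro) \
        else set()
    with_go = set(go["product_id"]) & products if len(go) else set()
    return {
        "products": len(products),
        "with_domain": len(with_domain),
        "with_go": len(with_go),
    }
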