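"""Ontology DAG handling, annotation up-propagation and term selection.

Works for any OBO ontology restricted to ``is_a`` edges (HPO for phenotype
terms, GO for the functional-similarity evaluation).  Also provides the
information-content machinery of the ontology-based baseline: the similarity
of two terms as the IC of their most informative common ancestor.
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from os import PathLike
from types import MappingProxyType
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)


class OntologyDAG:
    """A term hierarchy: directed acyclic graph of ``is_a`` (child, parent) edges."""

    def __init__(
        self,
        terms: Iterable[str],
        is_a_edges: Iterable[tuple[str, str]],
    ) -> None:
        self.terms = frozenset(terms)
        self.is_a_edges = frozenset((c, p) for c, p in is_a_edges)
        for c, p in self.is_a_edges:
            if c not in self.terms or p not in self.terms:
                raise ValueError(f"edge ({c!r}, {p!r}) references unknown term")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.is_a_edges)  # edges point child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a hierarchy contains a cycle")
        self._g = g

    @classmethod
    def from_obo(cls, path: str | PathLike) -> "OntologyDAG":
        """Read an OBO 1.2/1.4 flat file; obsolete terms are dropped."""
        g = obonet.read_obo(path)
        edges = {
            (child, parent)
            for child, parent, key in g.edges(keys=True)
            if key == "is_a"
        }
        return cls(set(g.nodes), edges)

    # -- traversal ---------------------------------------------------------

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._g.successors(term))

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._g.predecessors(term))

    def ancestors(self, term: str, include_self: bool = False) -> set[str]:
        """All terms reachable from ``term`` along is_a edges (more general)."""
        anc = nx.descendants(self._g, term)  # edges run child->parent
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str, include_self: bool = False) -> set[str]:
        desc = nx.ancestors(self._g, term)
        if include_self:
            desc.add(term)
        return desc

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if self._g.out_degree(t) == 0)

    def topological_order(self) -> list[str]:
        """Terms ordered children-before-parents."""
        return list(nx.topological_sort(self._g))

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OntologyDAG({len(self.terms)} terms, {len(self.is_a_edges)} is_a edges)"

    def to_obo(self, path: str | PathLike) -> None:
        """Write a minimal OBO 1.2 flat file (id, name, is_a) that round-trips."""
        parents: dict[str, list[str]] = defaultdict(list)
        for c, p in sorted(self.is_a_edges):
            parents[c].append(p)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("format-version: 1.2\n")
            for term in sorted(self.terms):
                fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
                for p in sorted(parents.get(term, [])):
                    fh.write(f"is_a: {p} ! {p}\n")


@dataclass(frozen=True, eq=False)
class AnnotationTable:
    """Term → gene-set mapping, optionally up-propagated along is_a edges."""

    term_to_genes: Mapping[str, frozenset[str]]
    propagated: bool = False

    def __post_init__(self) -> None:
        normalised = MappingProxyType(
            {t: frozenset(gs) for t, gs in dict(self.term_to_genes).items()}
        )
        object.__setattr__(self, "term_to_genes", normalised)

    def genes(self, term: str) -> frozenset[str]:
        return self.term_to_genes.get(term, frozenset())

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.term_to_genes)

    @property
    def all_genes(self) -> frozenset[str]:
        """Every gene annotated anywhere in the table (the IC denominator D)."""
        out: set[str] = set()
        for gs in self.term_to_genes.values():
            out |= gs
        return frozenset(out)

    def __contains__(self, term: str) -> bool:
        return term in self.term_to_genes


def propagate_annotations(dag: OntologyDAG, table: AnnotationTable) -> AnnotationTable:
    """Up-propagate annotations: each term gains its descendants' genes.

    After propagation every term's gene set is the union of its direct genes
    and the genes of all is_a descendants, so gene sets are nested along the
    hierarchy.  Terms annotated in the table but absent from the DAG are kept
    unchanged (and counted in the log).
    """
    if table.propagated:
        raise ValueError("annotation table is already propagated")
    acc: dict[str, set[str]] = defaultdict(set)
    for t, gs in table.term_to_genes.items():
        acc[t].update(gs)
    unknown = [t for t in acc if t not in dag]
    if unknown:
        logger.info(
            "propagate_annotations: %d annotated terms not in the DAG "
            "left unchanged", len(unknown),
        )
    for child in dag.topological_order():
        gs = acc.get(child)
        if not gs:
            continue
        for parent in dag.parents(child):
            acc[parent].update(gs)
    return AnnotationTable(
        {t: frozenset(gs) for t, gs in acc.items() if gs}, propagated=True
    )


def select_study_terms(
    dag: OntologyDAG, table: AnnotationTable, min_genes: int = 25
) -> list[str]:
    """Select phenotype terms for analysis.

    Keeps propagated terms with at least ``min_genes`` annotated genes (the
    incomplete-interactome percolation argument), then removes every term that
    is an ancestor of another retained term so no parent-child pair remains.
    Returns term ids in lexicographic order.
    """
    if not table.propagated:
        raise ValueError("select_study_terms requires a propagated table")
    kept = [
        t
        for t in sorted(table.term_to_genes)
        if t in dag and len(table.genes(t)) >= min_genes
    ]
    kept_set = set(kept)
    result = [
        t for t in kept if not (dag.descendants(t) & (kept_set - {t}))
    ]
    logger.info(
        "select_study_terms: %d terms >= %d genes, %d after ancestor removal",
        len(kept), min_genes, len(result),
    )
    return result


def information_content(term: str, table: AnnotationTable) -> float:
    """IC(t) = -ln(|D_t| / D), D the total annotated-gene count of the table."""
    genes = table.genes(term)
    if not genes:
        raise ValueError(f"term {term!r} has no annotated genes")
    total = len(table.all_genes)
    return -math.log(len(genes) / total)


def ic_lca_similarity(
    t1: str, t2: str, dag: OntologyDAG, table: AnnotationTable
) -> float:
    """Similarity of two terms as the IC of their most informative common ancestor.

    The most informative common ancestor is the shared ancestor (terms count
    as their own ancestors) with maximal IC, equivalently the smallest
    annotated-gene set; ties in |D_t| give identical scores.
    """
    if t1 not in dag or t2 not in dag:
        raise ValueError("both terms must be in the ontology")
    common = dag.ancestors(t1, include_self=True) & dag.ancestors(t2, include_self=True)
    if not common:
        raise ValueError(f"{t1!r} and {t2!r} share no common ancestor")
    counts = [len(table.genes(t)) for t in common if table.genes(t)]
    if not counts:
        raise ValueError(
            f"no annotated common ancestor for {t1!r} and {t2!r}"
        )
    return -math.log(min(counts) / len(table.all_genes))
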