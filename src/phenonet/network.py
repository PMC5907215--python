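"""Undirected protein-protein interaction network container.

The interactome is modelled as a simple undirected graph: nodes are opaque
protein/gene identifiers, edges are physical interactions.  The class is a
thin wrapper around :class:`networkx.Graph` that enforces simplicity
(no self-loops, no parallel edges) on construction.
"""
from __future__ import annotations

from collections.abc import Hashable, Iterable

import networkx as nx

Node = Hashable


class InteractionNetwork:
    """A simple undirected interaction network N(V, E)."""

    __slots__ = ("_graph",)

    def __init__(self, graph: nx.Graph | None = None) -> None:
        if graph is None:
            graph = nx.Graph()
        if graph.is_directed() or graph.is_multigraph():
            raise ValueError("interaction networks are simple undirected graphs")
        graph.remove_edges_from(list(nx.selfloop_edges(graph)))
        self._graph = graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Node, Node]],
        nodes: Iterable[Node] = (),
    ) -> "InteractionNetwork":
        """Build a network from an edge iterable plus optional isolated nodes.

        Self-loops are dropped; duplicate and reversed-duplicate edges collapse
        to a single undirected edge.
        """
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((u, v) for u, v in edges if u != v)
        return cls(g)

    # -- views -------------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (shared, not a copy)."""
        return self._graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._graph.nodes)

    @property
    def edges(self) -> frozenset:
        """Edges as a set of unordered (frozenset) node pairs."""
        return frozenset(frozenset(e) for e in self._graph.edges)

    @property
    def number_of_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def number_of_edges(self) -> int:
        return self._graph.number_of_edges()

    def node_list(self) -> list:
        """Nodes in deterministic (sorted) order."""
        return sorted(self._graph.nodes)

    def edge_list(self) -> list[tuple]:
        """Edges as sorted tuples in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self._graph.edges)

    def adjacency(self) -> dict:
        """Plain adjacency mapping node -> tuple of neighbours.

        Used by permutation loops where attribute lookups on graph views
        dominate the runtime.
        """
        return {v: tuple(nbrs) for v, nbrs in self._graph.adj.items()}

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self._graph.copy())

    def __contains__(self, node: Node) -> bool:
        return node in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"InteractionNetwork({self.number_of_nodes} nodes, "
            f"{self.number_of_edges} edges)"
        )
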