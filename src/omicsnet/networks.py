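"""Typed-node network containers shared by the assembly, extraction and
refinement stages.

Nodes are identified as ``"<layer>:<feature>"`` so that, e.g., the methylation
of gene X and the expression of gene X are distinct vertices.  The integrative
network is fully directed (regulator -> target gene); the refined network
additionally carries undirected (reversible) regulations produced by the
equivalence-class labeling of the learned Bayesian network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

LAYERS = ("mrna", "mirna", "methylation", "cnv")


def node_id(layer: str, feature: str) -> str:
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    return f"{layer}:{feature}"


def split_node(node: str) -> tuple[str, str]:
    layer, _, feature = node.partition(":")
    if layer not in LAYERS or not feature:
        raise ValueError(f"malformed node id {node!r}")
    return layer, feature


def node_layer(node: str) -> str:
    return split_node(node)[0]


def layer_of(node: str) -> str | None:
    """Like :func:`node_layer` but returns None for untagged variable names."""
    layer, _, feature = node.partition(":")
    if layer in LAYERS and feature:
        return layer
    return None


@dataclass
class IntegrativeNetwork:
    """Directed regulator -> mRNA-target network.

    ``graph`` is an :class:`networkx.DiGraph` whose nodes carry a ``layer``
    attribute and whose edges carry ``weight`` (the refit regression
    coefficient) and ``adj_r2`` (the adjusted R^2 of the target's model).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_node(self, node: str) -> None:
        self.graph.add_node(node, layer=node_layer(node))

    def add_edge(self, source: str, target: str,
                 weight: float = 0.0, adj_r2: float = float("nan")) -> None:
        self.add_node(source)
        self.add_node(target)
        self.graph.add_edge(source, target, weight=float(weight),
                            adj_r2=float(adj_r2))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def nodes_by_layer(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {layer: [] for layer in LAYERS}
        for node, data in self.graph.nodes(data=True):
            out[data["layer"]].append(node)
        return out


@dataclass
class RefinedNetwork:
    """Result of Bayesian-network refinement.

    Compelled regulations live in ``graph`` (directed); reversible ones in
    ``undirected_edges`` as frozen pairs.  ``score`` is the network score of
    the learned DAG and ``whitelist`` the prior edge set pinned during search.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    undirected_edges: set[frozenset] = field(default_factory=set)
    score: float = float("nan")
    whitelist: object = None  # PriorEdgeSet; kept loose to avoid an import cycle

    def add_node(self, node: str) -> None:
        self.graph.add_node(node, layer=layer_of(node))

    def add_directed(self, source: str, target: str) -> None:
        self.add_node(source)
        self.add_node(target)
        self.graph.add_edge(source, target)

    def add_undirected(self, a: str, b: str) -> None:
        self.add_node(a)
        self.add_node(b)
        self.undirected_edges.add(frozenset((a, b)))

    @property
    def directed_edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def all_pairs(self) -> set[frozenset]:
        """Skeleton of the refined graph (directed + undirected pairs)."""
        pairs = {frozenset(e) for e in self.graph.edges()}
        return pairs | set(self.undirected_edges)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("directed part of refined network is cyclic")
        overlap = {frozenset(e) for e in self.graph.edges()} & self.undirected_edges
        if overlap:
            raise ValueError(f"edges both directed and undirected: {overlap}")

    def nodes_by_layer(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {layer: [] for layer in LAYERS}
        for node, data in self.graph.nodes(data=True):
            if data.get("layer") in out:
                out[data["layer"]].append(node)
        return out
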