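"""Assemble per-gene regression models into the whole-genome integrative
network.

A gene's model contributes edges only if its adjusted R^2 reaches the cutoff
(inclusive; default 0.4).  Each selected regulator becomes one directed edge
regulator -> mrna:gene weighted by the refit coefficient and annotated with
the model's adjusted R^2.  Isolated nodes are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .networks import IntegrativeNetwork, node_id
from .vif_regression import RegressionResult

DEFAULT_CUTOFF = 0.4


def assemble(results: list[RegressionResult],
             cutoff: float = DEFAULT_CUTOFF) -> IntegrativeNetwork:
    """Union of all passing models' edges (adj_r2 >= cutoff, inclusive)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    net = IntegrativeNetwork()
    for res in results:
        if not res.usable or res.adj_r2 < cutoff or not res.selected:
            continue
        target = node_id("mrna", res.target_gene)
        for reg_node, coef in res.selected:
            net.add_edge(reg_node, target, weight=coef, adj_r2=res.adj_r2)
    return net


@dataclass
class NetworkStats:
    n_mrna: int
    n_mirna: int
    n_methylation: int
    n_cnv: int
    n_edges: int
    degree: dict[str, int]

    @property
    def n_nodes(self) -> int:
        return self.n_mrna + self.n_mirna + self.n_methylation + self.n_cnv


def network_stats(net: IntegrativeNetwork) -> NetworkStats:
    """Node counts by molecular layer plus the total degree per node."""
    by_layer = net.nodes_by_layer()
    return NetworkStats(
        n_mrna=len(by_layer["mrna"]),
        n_mirna=len(by_layer["mirna"]),
        n_methylation=len(by_layer["methylation"]),
        n_cnv=len(by_layer["cnv"]),
        n_edges=net.n_edges,
        degree={n: d for n, d in net.graph.degree()},
    )


def edge_recovery(net: IntegrativeNetwork,
                  true_pairs: set[tuple[str, str]]) -> tuple[float, float]:
    """(precision, recall) of the network's edges against ground-truth
    (regulator_node, target_gene) pairs."""
    found = {(u, v.partition(":")[2]) for u, v in net.edge_set()}
    if not found:
        return (1.0 if not true_pairs else 0.0, 0.0 if true_pairs else 1.0)
    tp = len(found & true_pairs)
    precision = tp / len(found)
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return precision, recall
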