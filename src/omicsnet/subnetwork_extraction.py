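"""Isolate the subnetwork of seed (pathway) genes and their direct
regulators from the whole-genome integrative network.

"Direct regulators" means one-hop in-neighbors of the seed genes' mRNA nodes;
regulators of regulators are excluded.  Known prior regulations between seed
genes can be merged in so the downstream Bayesian stage can pin them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import PriorEdgeSet
from .networks import IntegrativeNetwork, node_id

logger = logging.getLogger(__name__)


@dataclass
class SubnetworkSpec:
    seed_genes: set[str]
    include_prior_edges: bool = True

    def __post_init__(self) -> None:
        if not self.seed_genes:
            raise ValueError("seed gene set is empty")


def extract(net: IntegrativeNetwork, spec: SubnetworkSpec,
            prior: PriorEdgeSet | None = None) -> IntegrativeNetwork:
    """Seed mRNA nodes, their in-neighbors, the induced VIF edges, and
    (optionally) the prior gene-gene edges mapped onto mRNA nodes."""
    prior = prior or PriorEdgeSet()
    prior_genes = ({g for e in prior.edges for g in e}
                   if spec.include_prior_edges else set())
    present: set[str] = set()
    missing: set[str] = set()
    for gene in sorted(spec.seed_genes):
        node = node_id("mrna", gene)
        if net.graph.has_node(node) or gene in prior_genes:
            present.add(gene)
        else:
            missing.add(gene)
    if not present:
        raise ValueError("no seed gene is present in the network or the "
                         "prior edge set")
    if missing:
        logger.warning("seed genes absent from network and prior: %s",
                       sorted(missing))

    sub = IntegrativeNetwork()
    seed_nodes = {node_id("mrna", g) for g in present}
    for node in seed_nodes:
        sub.add_node(node)
    for node in sorted(seed_nodes):
        if not net.graph.has_node(node):
            continue
        for reg in net.graph.predecessors(node):
            data = net.graph.edges[reg, node]
            sub.add_edge(reg, node, weight=data.get("weight", 0.0),
                         adj_r2=data.get("adj_r2", float("nan")))
    # VIF edges between two seed genes' mRNA nodes are part of the induced
    # subgraph as well (an mRNA node can appear as a regulator only through
    # the prior, so this is usually empty).
    if spec.include_prior_edges:
        for src, dst in prior.edges:
            if src in present and dst in present:
                sub.add_edge(node_id("mrna", src), node_id("mrna", dst),
                             weight=0.0, adj_r2=float("nan"))
    return sub
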