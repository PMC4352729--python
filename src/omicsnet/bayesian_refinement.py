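"""Score-based Bayesian-network refinement of the extracted subnetwork.

The subnetwork's variables (mRNA expression, miRNA expression, methylation
level, copy-number call — the last treated as continuous) are modeled as a
linear-Gaussian Bayesian network.  Structure search is hill-climbing with
random restarts over DAGs that (i) contain every whitelisted prior edge,
(ii) respect a parent-count cap, and (iii) optionally only use edges
proposed by the VIF stage, the prior, or their reversals.  By default the
search is unrestricted over the subnetwork's nodes: modeling regulation
*between* feature variables is what lets the refinement explain away a
spurious regulator -> gene edge whose correlation is mediated by another
regulator.  The decomposable Gaussian BIC score is

    score(G) = sum_v [ loglik(v | Pa_v) - (|Pa_v| + 2)/2 * log n ]

where loglik is the profile log-likelihood of the OLS fit of v on its
parents.  The learned DAG is then reduced to its Markov-equivalence class:
compelled edges (same orientation in every equivalent DAG, plus all
whitelisted edges, whose orientations are propagated with Meek's rules) are
reported directed; reversible edges are reported undirected.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import MultiOmicsDataset, PriorEdgeSet
from .networks import (IntegrativeNetwork, RefinedNetwork, layer_of, node_id)

_EPS = 1e-9


@dataclass
class BNConfig:
    score: str = "bic_gaussian"        # or "loglik_gaussian"
    restarts: int = 10
    max_parents: int = 5
    candidate_edges_only: bool = False
    layer_blacklist: bool = False      # forbid edges into cnv / methylation
    perturb_edges: int = 3             # random edge tweaks per restart
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.score not in ("bic_gaussian", "loglik_gaussian"):
            raise ValueError(f"unknown score {self.score!r}")


class _GaussianScore:
    """Decomposable Gaussian log-likelihood / BIC with local-score caching."""

    def __init__(self, data: pd.DataFrame, kind: str = "bic_gaussian"):
        # data: variables x samples
        self.names = list(data.index)
        arr = data.to_numpy(dtype=float)
        keep = np.isfinite(arr).all(axis=0)
        self.X = arr[:, keep]
        self.n = self.X.shape[1]
        self.kind = kind
        self.idx = {v: i for i, v in enumerate(self.names)}
        self._cache: dict[tuple[int, frozenset], float] = {}

    def local(self, v: str, parents: frozenset) -> float:
        key = (self.idx[v], frozenset(self.idx[p] for p in parents))
        if key in self._cache:
            return self._cache[key]
        y = self.X[key[0]]
        if key[1]:
            P = self.X[sorted(key[1])].T
            design = np.column_stack([np.ones(self.n), P])
        else:
            design = np.ones((self.n, 1))
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sigma2 = max(float(resid @ resid) / self.n, 1e-300)
        ll = -0.5 * self.n * (np.log(2 * np.pi * sigma2) + 1.0)
        if self.kind == "bic_gaussian":
            ll -= 0.5 * (len(key[1]) + 2) * np.log(self.n)
        self._cache[key] = ll
        return ll

    def total(self, dag: nx.DiGraph) -> float:
        return sum(self.local(v, frozenset(dag.predecessors(v)))
                   for v in self.names)


def _allowed(u: str, v: str, allowed_pairs: set | None,
             layer_blacklist: bool) -> bool:
    if u == v:
        return False
    if allowed_pairs is not None and (u, v) not in allowed_pairs:
        return False
    if layer_blacklist and layer_of(v) in ("cnv", "methylation"):
        return False
    return True


def _hill_climb(dag: nx.DiGraph, score: _GaussianScore,
                whitelist_edges: set[tuple[str, str]],
                cfg: BNConfig, allowed_pairs: set | None) -> float:
    """Greedy add/delete/reverse moves until no move improves the score."""
    names = score.names
    current = {v: score.local(v, frozenset(dag.predecessors(v)))
               for v in names}
    if allowed_pairs is None:
        move_pairs = [(u, v) for u in names for v in names if u != v]
    else:
        move_pairs = sorted(allowed_pairs)
    while True:
        best_delta, best_move = _EPS, None
        # descendants once per sweep: adding u->v is acyclic iff u is not
        # reachable from v
        desc = {v: nx.descendants(dag, v) for v in names}
        parents = {v: frozenset(dag.predecessors(v)) for v in names}
        for u, v in move_pairs:
            if not dag.has_edge(u, v):
                if dag.has_edge(v, u):
                    continue
                if not _allowed(u, v, allowed_pairs, cfg.layer_blacklist):
                    continue
                if len(parents[v]) >= cfg.max_parents or u in desc[v]:
                    continue
                delta = score.local(v, parents[v] | {u}) - current[v]
                if delta > best_delta:
                    best_delta, best_move = delta, ("add", u, v)
        for u, v in list(dag.edges()):
            if (u, v) in whitelist_edges:
                continue
            d_del = score.local(v, parents[v] - {u}) - current[v]
            if d_del > best_delta:
                best_delta, best_move = d_del, ("del", u, v)
            # reversal = delete u->v then add v->u
            if (_allowed(v, u, allowed_pairs, cfg.layer_blacklist)
                    and len(parents[u]) < cfg.max_parents):
                dag.remove_edge(u, v)
                cyclic = nx.has_path(dag, u, v)
                dag.add_edge(u, v)
                if not cyclic:
                    d_rev = (d_del + score.local(u, parents[u] | {v})
                             - current[u])
                    if d_rev > best_delta:
                        best_delta, best_move = d_rev, ("rev", u, v)
        if best_move is None:
            return sum(current.values())
        op, u, v = best_move
        if op == "add":
            dag.add_edge(u, v)
        elif op == "del":
            dag.remove_edge(u, v)
        else:
            dag.remove_edge(u, v)
            dag.add_edge(v, u)
            current[u] = score.local(u, frozenset(dag.predecessors(u)))
        current[v] = score.local(v, frozenset(dag.predecessors(v)))


def learn_structure(data: pd.DataFrame, whitelist: PriorEdgeSet | None,
                    cfg: BNConfig | None = None,
                    allowed_pairs: set[tuple[str, str]] | None = None,
                    whitelist_edges: set[tuple[str, str]] | None = None
                    ) -> nx.DiGraph:
    """Learn a DAG over the rows of ``data`` (variables x samples).

    ``whitelist`` holds prior gene-gene regulations whose endpoints are plain
    gene symbols; they are mapped onto ``mrna:`` nodes when present.  Already
    node-qualified pins can be passed via ``whitelist_edges`` instead.
    Deterministic under a fixed ``cfg.seed``.
    """
    cfg = cfg or BNConfig()
    names = list(data.index)
    if len(names) < 3:
        raise ValueError("structure learning needs >= 3 variables")
    score = _GaussianScore(data, cfg.score)
    if score.n < 10:
        raise ValueError("structure learning needs >= 10 complete samples")

    pins: set[tuple[str, str]] = set(whitelist_edges or set())
    if whitelist is not None:
        for src, dst in whitelist.edges:
            u = src if src in score.idx else node_id("mrna", src)
            v = dst if dst in score.idx else node_id("mrna", dst)
            if u not in score.idx or v not in score.idx:
                raise ValueError(f"whitelist edge {src}->{dst} references a "
                                 "variable absent from the data")
            pins.add((u, v))
    base = nx.DiGraph()
    base.add_nodes_from(names)
    base.add_edges_from(pins)
    if not nx.is_directed_acyclic_graph(base):
        raise ValueError("whitelist edges form a cycle")
    if allowed_pairs is not None:
        allowed_pairs = set(allowed_pairs) | pins

    rng = np.random.default_rng(np.random.SeedSequence(
        [int(cfg.seed) & 0x7FFFFFFF, 0xB17]))
    pool = (sorted(allowed_pairs) if allowed_pairs is not None
            else [(u, v) for u in names for v in names if u != v])

    best_dag, best_score = None, -np.inf
    for restart in range(cfg.restarts):
        dag = base.copy()
        if restart > 0 and pool:
            for _ in range(cfg.perturb_edges):
                u, v = pool[rng.integers(len(pool))]
                if (dag.has_edge(u, v) or dag.has_edge(v, u)
                        or dag.in_degree(v) >= cfg.max_parents
                        or not _allowed(u, v, allowed_pairs,
                                        cfg.layer_blacklist)
                        or nx.has_path(dag, v, u)):
                    continue
                dag.add_edge(u, v)
        final = _hill_climb(dag, score, pins, cfg, allowed_pairs)
        if final > best_score + _EPS:
            best_dag, best_score = dag, final
    best_dag.graph["score"] = best_score
    return best_dag


# ---------------------------------------------------------------------------
# DAG -> CPDAG (compelled / reversible labeling)
# ---------------------------------------------------------------------------

def _order_edges(dag: nx.DiGraph) -> list[tuple[str, str]]:
    topo = {v: i for i, v in enumerate(nx.topological_sort(dag))}
    ordered: list[tuple[str, str]] = []
    unordered = set(dag.edges())
    while unordered:
        y = min((e[1] for e in unordered), key=lambda v: topo[v])
        x = max((u for u, v in unordered if v == y), key=lambda v: topo[v])
        ordered.append((x, y))
        unordered.discard((x, y))
    return ordered


def _label_compelled(dag: nx.DiGraph) -> set[tuple[str, str]]:
    """Chickering's labeling: returns the set of compelled edges."""
    order = _order_edges(dag)
    label: dict[tuple[str, str], str] = {}
    for x, y in order:
        if (x, y) in label:
            continue
        done = False
        for w in dag.predecessors(x):
            if label.get((w, x)) != "compelled":
                continue
            if not dag.has_edge(w, y):
                for z in dag.predecessors(y):
                    label[(z, y)] = "compelled"
                done = True
                break
            label[(w, y)] = "compelled"
        if done:
            continue
        if any(z != x and not dag.has_edge(z, x)
               for z in dag.predecessors(y)):
            mark = "compelled"
        else:
            mark = "reversible"
        for z in dag.predecessors(y):
            label.setdefault((z, y), mark)
        label[(x, y)] = label.get((x, y), mark)
    return {e for e, m in label.items() if m == "compelled"}


def _meek_close(directed: set[tuple[str, str]],
                undirected: set[frozenset]) -> tuple[set, set]:
    """Propagate orientations (Meek rules R1-R4) after pinning edges."""
    directed = set(directed)
    undirected = {frozenset(p) for p in undirected}

    def adjacent(a, b):
        return ((a, b) in directed or (b, a) in directed
                or frozenset((a, b)) in undirected)

    changed = True
    while changed:
        changed = False
        for pair in list(undirected):
            a, b = tuple(pair)
            for x, y in ((a, b), (b, a)):
                # R1: w -> x, w and y nonadjacent  =>  x -> y
                r1 = any((w, x) in directed and not adjacent(w, y)
                         for w in {e[0] for e in directed if e[1] == x})
                # R2: x -> w -> y  =>  x -> y
                r2 = any((x, w) in directed and (w, y) in directed
                         for w in {e[1] for e in directed if e[0] == x})
                # R3: x - c, x - d, c -> y, d -> y, c,d nonadjacent => x -> y
                cands = [c for c in {e[0] for e in directed if e[1] == y}
                         if frozenset((x, c)) in undirected]
                r3 = any(not adjacent(c, d)
                         for i, c in enumerate(cands)
                         for d in cands[i + 1:])
                # R4: x - d, d -> c, c -> y, x,c adjacent, d,y nonadj => x->y
                r4 = any(frozenset((x, d)) in undirected
                         and (d, c) in directed and (c, y) in directed
                         and adjacent(x, c) and not adjacent(d, y)
                         for (d, c) in directed if (c, y) in directed)
                if r1 or r2 or r3 or r4:
                    undirected.discard(pair)
                    directed.add((x, y))
                    changed = True
                    break
            if pair not in undirected:
                continue
    return directed, undirected


def to_cpdag(dag: nx.DiGraph,
             whitelist_edges: set[tuple[str, str]] | None = None
             ) -> RefinedNetwork:
    """Reduce a learned DAG to compelled (directed) and reversible
    (undirected) regulations, with whitelisted edges pinned directed."""
    pins = set(whitelist_edges or set())
    compelled = _label_compelled(dag) | (pins & set(dag.edges()))
    undirected = {frozenset(e) for e in dag.edges()
                  if e not in compelled}
    directed, undirected = _meek_close(compelled, undirected)

    net = RefinedNetwork(score=float(dag.graph.get("score", float("nan"))))
    for v in dag.nodes():
        net.add_node(v)
    for u, v in sorted(directed):
        net.add_directed(u, v)
    for pair in undirected:
        a, b = sorted(pair)
        net.add_undirected(a, b)
    net.validate()
    return net


def refine(subnet: IntegrativeNetwork, dataset: MultiOmicsDataset,
           prior: PriorEdgeSet | None = None,
           cfg: BNConfig | None = None) -> RefinedNetwork:
    """Assemble the subnetwork's node x sample matrix, learn the Bayesian
    network with prior edges pinned, and return its equivalence-class graph.

    Subnetwork edges that the learned structure does not support are thereby
    dropped (the regression stage's false-positive pruning)."""
    cfg = cfg or BNConfig()
    prior = prior or PriorEdgeSet()
    nodes = sorted(subnet.graph.nodes())
    if not nodes:
        raise ValueError("empty subnetwork")
    rows = {}
    for node in nodes:
        try:
            rows[node] = dataset.node_values(node)
        except KeyError as exc:
            raise ValueError(f"subnetwork node {node!r} cannot be resolved "
                             "to a data row") from exc
    data = pd.DataFrame(rows, index=dataset.sample_ids).T

    pins = {(node_id("mrna", s), node_id("mrna", t))
            for s, t in prior.edges
            if node_id("mrna", s) in rows and node_id("mrna", t) in rows}
    allowed = None
    if cfg.candidate_edges_only:
        vif_edges = set(subnet.graph.edges())
        allowed = (vif_edges | pins
                   | {(v, u) for u, v in vif_edges | pins})
    dag = learn_structure(data, None, cfg, allowed_pairs=allowed,
                          whitelist_edges=pins)
    refined = to_cpdag(dag, whitelist_edges=pins)
    refined.whitelist = prior
    return refined
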