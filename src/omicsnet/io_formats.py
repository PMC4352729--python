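"""Reading and writing the omics matrices, prior-edge lists, survival tables
and network files, plus the four-way sample intersection.

All tabular formats are plain TSV (tab-separated, UTF-8, ``.`` decimal, no
quoting), matching common TCGA-style matrix exports: a header row of sample
IDs, a first column of feature IDs, and a numeric body in which empty cells
denote missing values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .networks import (LAYERS, IntegrativeNetwork, RefinedNetwork,
                       node_layer, split_node)

NETWORK_FORMATS = ("sif", "graphml", "edge_tsv")

_CNV_STATES = frozenset((-2.0, -1.0, 0.0, 1.0, 2.0))


class FormatError(ValueError):
    """Malformed input file (structure, not values)."""


class ValidationError(ValueError):
    """Well-formed file whose values violate the layer's declared support."""


@dataclass
class OmicsLayer:
    """One feature x sample numeric matrix tagged with its molecular layer.

    ``values`` is a pandas DataFrame indexed by feature ID with sample-ID
    columns; missing measurements are NaN.
    """

    layer_tag: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer_tag not in LAYERS:
            raise ValueError(f"unknown layer tag {self.layer_tag!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate feature IDs in {self.layer_tag} "
                              f"layer: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            raise FormatError(f"duplicate sample IDs in {self.layer_tag} layer")
        self.values = self.values.astype(float)
        self._validate_support()

    def _validate_support(self) -> None:
        arr = self.values.to_numpy()
        finite = arr[np.isfinite(arr)]
        if self.layer_tag == "cnv":
            bad = ~np.isin(finite, list(_CNV_STATES))
            if bad.any():
                raise ValidationError(
                    f"cnv layer contains values outside {{-2..2}}: "
                    f"{np.unique(finite[bad])[:5]}")
        elif self.layer_tag == "methylation":
            if ((finite < 0) | (finite > 1)).any():
                raise ValidationError(
                    "methylation layer contains values outside [0, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict_samples(self, samples: list[str]) -> "OmicsLayer":
        return OmicsLayer(self.layer_tag, self.values.loc[:, samples].copy())


@dataclass
class MultiOmicsDataset:
    """Four omics layers aligned on the common sample set, in a fixed order."""

    mrna: OmicsLayer
    mirna: OmicsLayer
    methylation: OmicsLayer
    cnv: OmicsLayer
    sample_ids: list[str]

    def __post_init__(self) -> None:
        for layer in self.layers():
            if layer.sample_ids != list(self.sample_ids):
                raise ValueError(
                    f"layer {layer.layer_tag} samples do not match the "
                    "dataset's common sample list")

    def layers(self) -> tuple[OmicsLayer, ...]:
        return (self.mrna, self.mirna, self.methylation, self.cnv)

    def regulator_layers(self) -> tuple[OmicsLayer, ...]:
        return (self.mirna, self.methylation, self.cnv)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def node_values(self, node: str) -> np.ndarray:
        """Per-sample values for a ``layer:feature`` node."""
        layer_tag, feature = split_node(node)
        layer = getattr(self, layer_tag)
        if feature not in layer.values.index:
            raise KeyError(f"feature {feature!r} not in {layer_tag} layer")
        return layer.values.loc[feature].to_numpy()


@dataclass
class PriorEdgeSet:
    """Known directed gene-gene regulations among a set of seed genes."""

    edges: list[tuple[str, str]] = field(default_factory=list)
    seed_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = set()
        for src, dst in self.edges:
            if src == dst:
                raise ValueError(f"self-loop prior edge {src}->{dst}")
            if (src, dst) in seen:
                raise ValueError(f"duplicate prior edge {src}->{dst}")
            seen.add((src, dst))
            if src not in self.seed_genes or dst not in self.seed_genes:
                raise ValueError(
                    f"prior edge {src}->{dst} has an endpoint outside the "
                    "seed gene set")


def read_layer(path: str | Path, layer_tag: str) -> OmicsLayer:
    """Read one omics matrix from TSV and validate it for its layer."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise FormatError(
            f"non-numeric cell {df.iat[r, c]!r} at feature "
            f"{df.index[r]!r}, sample {df.columns[c]!r} in {path}")
    return OmicsLayer(layer_tag, numeric)


def write_layer(layer: OmicsLayer, path: str | Path) -> None:
    layer.values.to_csv(path, sep="\t", index_label="feature")


def intersect_samples(mrna: OmicsLayer, mirna: OmicsLayer,
                      methylation: OmicsLayer, cnv: OmicsLayer
                      ) -> MultiOmicsDataset:
    """Restrict all four layers to their common samples (sorted).

    Mirrors the study design of keeping only patients measured on every
    platform; raises if no sample is shared by all four layers.
    """
    common = (set(mrna.sample_ids) & set(mirna.sample_ids)
              & set(methylation.sample_ids) & set(cnv.sample_ids))
    if not common:
        raise ValueError("no sample is present in all four layers")
    order = sorted(common)
    return MultiOmicsDataset(
        mrna=mrna.restrict_samples(order),
        mirna=mirna.restrict_samples(order),
        methylation=methylation.restrict_samples(order),
        cnv=cnv.restrict_samples(order),
        sample_ids=order,
    )


def read_seed_genes(path: str | Path) -> set[str]:
    """One gene symbol per line; '#' comments and blank lines ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


def read_prior_edges(path: str | Path,
                     seed_genes: set[str] | None = None) -> PriorEdgeSet:
    """Two-column TSV (source, target) of known directed regulations."""
    edges: list[tuple[str, str]] = []
    genes: set[str] = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{ln}: expected two tab-separated "
                              f"columns, got {line!r}")
        src, dst = parts[0].strip(), parts[1].strip()
        edges.append((src, dst))
        genes.update((src, dst))
    seeds = set(seed_genes) | genes if seed_genes is not None else genes
    return PriorEdgeSet(edges=edges, seed_genes=seeds)


def write_prior_edges(prior: PriorEdgeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, dst in prior.edges:
            fh.write(f"{src}\t{dst}\n")


def table1_sample_ids() -> list[str]:
    """The packaged transcription of the study's 129-patient sample list."""
    text = (importlib.resources.files("omicsnet.data")
            / "tcga_lusc_table1_samples.txt").read_text()
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# Network serialization
# ---------------------------------------------------------------------------

def _network_parts(net: IntegrativeNetwork | RefinedNetwork):
    """Normalize either network type to (nodes, directed, undirected)."""
    if isinstance(net, RefinedNetwork):
        directed = [(u, v, {}) for u, v in sorted(net.graph.edges())]
        undirected = [tuple(sorted(pair)) for pair in net.undirected_edges]
        nodes = set(net.graph.nodes())
        for pair in undirected:
            nodes.update(pair)
        return sorted(nodes), directed, sorted(undirected)
    nodes = sorted(net.graph.nodes())
    directed = [(u, v, net.graph.edges[u, v]) for u, v in sorted(net.graph.edges())]
    return nodes, directed, []


def write_network(net: IntegrativeNetwork | RefinedNetwork,
                  path: str | Path, format: str = "edge_tsv") -> None:
    """Serialize a network; node IDs embed the layer tag so every format
    round-trips layer information."""
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; "
                         f"choose one of {NETWORK_FORMATS}")
    nodes, directed, undirected = _network_parts(net)
    path = Path(path)
    if format == "sif":
        linked = {n for e in directed for n in e[:2]}
        linked.update(n for pair in undirected for n in pair)
        with open(path, "w") as fh:
            for u, v, _ in directed:
                fh.write(f"{u}\tregulates\t{v}\n")
            for a, b in undirected:
                fh.write(f"{a}\tassociated\t{b}\n")
            for n in nodes:
                if n not in linked:
                    fh.write(f"{n}\n")
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\trelation\ttarget\tweight\tadj_r2\n")
            for u, v, data in directed:
                w = data.get("weight", "")
                r2 = data.get("adj_r2", "")
                fh.write(f"{u}\tdirected\t{v}\t{w}\t{r2}\n")
            for a, b in undirected:
                fh.write(f"{a}\tundirected\t{b}\t\t\n")
            linked = {n for e in directed for n in e[:2]}
            linked.update(n for pair in undirected for n in pair)
            for n in nodes:
                if n not in linked:
                    fh.write(f"{n}\tisolated\t\t\t\n")
    else:  # graphml
        g = nx.DiGraph()
        for n in nodes:
            g.add_node(n, layer=node_layer(n))
        for u, v, data in directed:
            g.add_edge(u, v, directed=True,
                       weight=float(data.get("weight", float("nan"))),
                       adj_r2=float(data.get("adj_r2", float("nan"))))
        for a, b in undirected:
            g.add_edge(a, b, directed=False)
        nx.write_graphml(g, path)


def read_network(path: str | Path, format: str = "edge_tsv"
                 ) -> IntegrativeNetwork | RefinedNetwork:
    """Inverse of :func:`write_network`.

    Returns an :class:`IntegrativeNetwork` when every edge is directed,
    otherwise a :class:`RefinedNetwork` (score unknown, no whitelist).
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}")
    nodes: list[str] = []
    directed: list[tuple[str, str, float, float]] = []
    undirected: list[tuple[str, str]] = []
    path = Path(path)
    if format == "sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                nodes.append(parts[0])
            elif parts[1] == "regulates":
                directed.append((parts[0], parts[2], float("nan"), float("nan")))
            elif parts[1] == "associated":
                undirected.append((parts[0], parts[2]))
            else:
                raise FormatError(f"unknown SIF relation {parts[1]!r}")
    elif format == "edge_tsv":
        lines = path.read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            u, rel, v, w, r2 = (line.split("\t") + [""] * 5)[:5]
            if rel == "directed":
                directed.append((u, v, float(w) if w else float("nan"),
                                 float(r2) if r2 else float("nan")))
            elif rel == "undirected":
                undirected.append((u, v))
            elif rel == "isolated":
                nodes.append(u)
            else:
                raise FormatError(f"unknown relation {rel!r} in {path}")
    else:
        g = nx.read_graphml(path)
        for n in g.nodes():
            nodes.append(n)
        for u, v, data in g.edges(data=True):
            if data.get("directed", True):
                directed.append((u, v, float(data.get("weight", float("nan"))),
                                 float(data.get("adj_r2", float("nan")))))
            else:
                undirected.append((u, v))
    if undirected:
        net = RefinedNetwork()
        for n in nodes:
            net.add_node(n)
        for u, v, _, _ in directed:
            net.add_directed(u, v)
        for a, b in undirected:
            net.add_undirected(a, b)
        return net
    inet = IntegrativeNetwork()
    for n in nodes:
        inet.add_node(n)
    for u, v, w, r2 in directed:
        inet.add_edge(u, v, weight=w, adj_r2=r2)
    return inet
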