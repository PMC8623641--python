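"""Proportional-threshold binarization and local graph parameters.

A real-valued connectivity matrix is binarized by keeping the strongest
fixed *proportion* of connections (proportional threshold, PT), which
equalizes edge density across subjects, and five node-level parameters are
computed on the resulting undirected binary graph:

* degree ``K_i`` -- number of surviving neighbours;
* clustering coefficient ``CC_i`` -- fraction of realized links among the
  neighbours of *i* (2 T_i / (k_i (k_i - 1)));
* characteristic path length ``L_i`` -- mean shortest-path distance from
  *i* to the other nodes;
* local efficiency ``Eff_i`` -- mean inverse shortest-path distance between
  neighbours of *i*, distances taken in the subgraph induced by those
  neighbours;
* betweenness ``BW_i`` -- fraction of shortest paths passing through *i*,
  normalized by ``1/(n (n-1))`` over ordered endpoint pairs.

Shortest-path machinery is delegated to networkx; the PT rule and the
normalization conventions are defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "BinaryGraph",
    "NodeMetricVector",
    "GRAPH_PARAMS",
    "proportional_threshold",
    "degree",
    "clustering_coefficient",
    "path_length",
    "local_efficiency",
    "betweenness",
    "node_metric",
]

GRAPH_PARAMS = ("K", "CC", "L", "Eff", "BW")


@dataclass
class BinaryGraph:
    """Undirected binary adjacency obtained from proportional thresholding."""

    adjacency: np.ndarray  # (n, n) in {0, 1}, symmetric, zero diagonal
    pt: float
    channel_labels: list[str] | None = None

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise ValueError("adjacency must be symmetric with a zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = A.astype(int)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        return g

    def edge_list_tsv(self, path) -> None:
        labels = self.channel_labels or [str(i) for i in range(self.n_nodes)]
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for i, j in zip(*np.triu_indices(self.n_nodes, 1)):
                if self.adjacency[i, j]:
                    fh.write(f"{labels[i]}\t{labels[j]}\n")


@dataclass
class NodeMetricVector:
    """Per-node values of one graph parameter."""

    parameter: str  # one of GRAPH_PARAMS
    values: np.ndarray
    channel_labels: list[str] | None = None

    def to_tsv(self, path) -> None:
        labels = self.channel_labels or [str(i) for i in range(len(self.values))]
        with open(path, "w") as fh:
            fh.write(f"channel\t{self.parameter}\n")
            for lab, v in zip(labels, self.values):
                fh.write(f"{lab}\t{v:.17g}\n")


def proportional_threshold(cm: ConnectivityMatrix | np.ndarray, pt: float) -> BinaryGraph:
    """Keep the strongest ``pt`` fraction of connections; binarize.

    The kept-edge count is ``round(pt * n(n-1)/2)`` with round-half-away-
    from-zero.  Ties at the cut are broken deterministically by ascending
    (row, col) index of the upper-triangle entry.
    """
    if isinstance(cm, ConnectivityMatrix):
        values, labels = cm.values, cm.channel_labels
    else:
        values, labels = np.asarray(cm, dtype=float), None
    if not 0 < pt < 1:
        raise ValueError("pt must lie strictly between 0 and 1")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = values[iu, ju]
    if np.all(w == w[0]):
        warnings.warn(
            "all connectivity values equal: PT selection is order-determined",
            RuntimeWarning,
        )
    n_edges = len(w)
    keep = int(np.floor(pt * n_edges + 0.5))
    # stable sort on -weight; equal weights retain ascending (row, col) order
    order = np.argsort(-w, kind="stable")[:keep]
    A = np.zeros((n, n), dtype=int)
    A[iu[order], ju[order]] = 1
    A += A.T
    return BinaryGraph(adjacency=A, pt=pt, channel_labels=labels)


def degree(g: BinaryGraph) -> NodeMetricVector:
    """Node degree K_i: row sums of the adjacency."""
    return NodeMetricVector("K", g.adjacency.sum(axis=1).astype(float), g.channel_labels)


def clustering_coefficient(g: BinaryGraph) -> NodeMetricVector:
    """Clustering coefficient CC_i, with CC_i = 0 when k_i < 2."""
    cc = nx.clustering(g.to_networkx())
    vals = np.array([cc[i] for i in range(g.n_nodes)], dtype=float)
    return NodeMetricVector("CC", vals, g.channel_labels)


def path_length(g: BinaryGraph, disconnected: str = "exclude") -> NodeMetricVector:
    """Mean shortest-path length L_i from each node.

    ``disconnected='exclude'`` (default) averages over reachable nodes only;
    ``'inf'`` propagates infinity whenever any node is unreachable.  Fully
    isolated nodes are flagged with +inf in either mode.
    """
    G = g.to_networkx()
    n = g.n_nodes
    vals = np.empty(n)
    for i in range(n):
        dists = nx.single_source_shortest_path_length(G, i)
        d = [dv for j, dv in dists.items() if j != i]
        if not d:
            vals[i] = np.inf
        elif disconnected == "inf" and len(d) < n - 1:
            vals[i] = np.inf
        else:
            vals[i] = float(np.mean(d))
    return NodeMetricVector("L", vals, g.channel_labels)


def local_efficiency(g: BinaryGraph) -> NodeMetricVector:
    """Local efficiency Eff_i, 0 when k_i < 2.

    Distances between neighbours of *i* are measured in the subgraph that
    contains only those neighbours (node *i* removed).
    """
    G = g.to_networkx()
    vals = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nbrs = list(G.neighbors(i))
        if len(nbrs) < 2:
            continue
        vals[i] = nx.global_efficiency(G.subgraph(nbrs))
    return NodeMetricVector("Eff", vals, g.channel_labels)


def betweenness(g: BinaryGraph) -> NodeMetricVector:
    """Betweenness BW_i with the 1/(n(n-1)) ordered-pair normalization."""
    n = g.n_nodes
    bw = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    # networkx counts unordered endpoint pairs for undirected graphs
    vals = np.array([2.0 * bw[i] / (n * (n - 1)) for i in range(n)])
    return NodeMetricVector("BW", vals, g.channel_labels)


_DISPATCH = {
    "K": degree,
    "CC": clustering_coefficient,
    "L": path_length,
    "Eff": local_efficiency,
    "BW": betweenness,
}


def node_metric(g: BinaryGraph, parameter: str) -> NodeMetricVector:
    """Compute one of the five local graph parameters by name."""
    try:
        return _DISPATCH[parameter](g)
    except KeyError:
        raise ValueError(
            f"unknown graph parameter {parameter!r}; choose from {GRAPH_PARAMS}"
        ) from None
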