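"""Trans-omic prior network.

The prior knowledge used by the modularity-constrained models is an undirected
graph over the p regression features (SNPs, genes and proteins), typically
built from SNP-to-gene promoter/TFBS relations and curated gene--gene /
gene--protein interactions.  This module holds the graph together with the
matrices the solvers need:

* adjacency ``G`` (symmetric, binary, zero diagonal),
* degree vector ``h`` and undirected edge count ``m``,
* Newman modularity matrix ``B`` with ``B_ij = G_ij - h_i h_j / (2m)``,
  which scores whether i and j are more connected than expected under a
  degree-preserving random rewiring,
* combinatorial Laplacian ``L = diag(h) - G``,
* the negative-semidefinite shift ``B - lambda_B I`` where ``lambda_B`` is
  the largest absolute eigenvalue of ``B`` (used to convexify the
  modularity penalty).

It also provides the subnetwork analyses applied to a fitted model's
selected features: induced connected components, shortest-path centralities,
and a subsampling procedure for centrality significance cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

VALID_LAYERS = ("SNP", "gene", "protein")

__all__ = [
    "TransOmicNetwork",
    "SubnetworkComponent",
    "NetworkError",
    "build_network",
    "modularity_matrix",
    "shift_negative_definite",
    "induced_components",
    "centralities",
    "rank_by_centrality",
    "subsampling_centrality_threshold",
]


class NetworkError(ValueError):
    """Raised for structurally invalid prior networks or queries."""


class TransOmicNetwork:
    """Undirected prior network over layered multi-omic features.

    Parameters
    ----------
    node_ids : sequence of str
        Feature identifiers; fixes the row/column order of ``G``, ``B``,
        ``L`` and ``h``.
    layers : mapping node -> {"SNP", "gene", "protein"}
    edges : iterable of (node, node[, interaction]) tuples
        Already deduplicated, undirected, self-loop free (``build_network``
        takes care of raw input).
    """

    def __init__(self, node_ids: Sequence[str], layers: Mapping[str, str], edges):
        self.node_ids: list[str] = list(node_ids)
        self.layers: dict[str, str] = dict(layers)
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for e in edges:
            a, b, *rest = e
            g.add_edge(a, b, interaction=rest[0] if rest else "interacts")
        self.graph = g

    # -- basic structure ---------------------------------------------------

    @property
    def p(self) -> int:
        return len(self.node_ids)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def index_of(self, node: str) -> int:
        return self._index[node]

    @cached_property
    def G(self) -> np.ndarray:
        """Symmetric binary adjacency in ``node_ids`` order."""
        return nx.to_numpy_array(self.graph, nodelist=self.node_ids, dtype=float)

    @cached_property
    def h(self) -> np.ndarray:
        """Node degrees (row sums of G)."""
        return self.G.sum(axis=1)

    @cached_property
    def m(self) -> int:
        """Number of undirected edges."""
        return int(round(self.h.sum() / 2.0))

    @cached_property
    def B(self) -> np.ndarray:
        """Modularity matrix ``B_ij = G_ij - h_i h_j / (2m)``."""
        if self.m == 0:
            raise NetworkError("network has no edges (m = 0), modularity undefined")
        h = self.h
        return self.G - np.outer(h, h) / (2.0 * self.m)

    @cached_property
    def L(self) -> np.ndarray:
        """Combinatorial Laplacian ``diag(h) - G`` (positive semidefinite)."""
        return np.diag(self.h) - self.G

    @cached_property
    def _shift(self) -> tuple[np.ndarray, float]:
        return shift_negative_definite(self.B)

    @property
    def lambda_B(self) -> float:
        """Largest absolute eigenvalue of B."""
        return self._shift[1]

    @property
    def B_shifted(self) -> np.ndarray:
        """``B - lambda_B I``; negative semidefinite."""
        return self._shift[0]

    # -- alignment with feature matrices -----------------------------------

    def embed(self, M: np.ndarray, feature_ids: Sequence[str]) -> np.ndarray:
        """Embed a p x p node-ordered matrix into ``feature_ids`` order.

        Features without a network node get zero rows/columns (they carry no
        network penalty); network nodes absent from ``feature_ids`` are
        simply not represented.
        """
        pf = len(feature_ids)
        out = np.zeros((pf, pf))
        pos = [(j, self._index[f]) for j, f in enumerate(feature_ids) if f in self._index]
        if pos:
            cols = np.array([j for j, _ in pos])
            rows = np.array([i for _, i in pos])
            out[np.ix_(cols, cols)] = M[np.ix_(rows, rows)]
        return out

    def degrees(self, nodes: Iterable[str] | None = None) -> pd.Series:
        if nodes is None:
            return pd.Series(self.h, index=self.node_ids, name="degree")
        return pd.Series({n: self.graph.degree[n] for n in nodes}, name="degree")


@dataclass(frozen=True)
class SubnetworkComponent:
    """A connected component of the prior network induced on selected nodes."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def build_network(
    edges: Iterable[tuple],
    layers: Mapping[str, str],
) -> TransOmicNetwork:
    """Build a :class:`TransOmicNetwork` from a raw edge list.

    Duplicate and reversed-duplicate edges are collapsed; self loops are
    dropped.  Every edge endpoint must carry a layer label.  Nodes present in
    ``layers`` but in no edge are retained as isolated (degree-0) nodes.
    """
    if not layers:
        raise NetworkError("network has no nodes: empty layer map")
    for node, layer in layers.items():
        if layer not in VALID_LAYERS:
            raise NetworkError(
                f"node {node!r} has invalid layer {layer!r}; expected one of {VALID_LAYERS}"
            )
    seen: set[frozenset] = set()
    clean = []
    for e in edges:
        a, b, *rest = e
        if a == b:
            continue
        missing = [n for n in (a, b) if n not in layers]
        if missing:
            raise NetworkError(f"edge endpoint(s) without layer label: {missing}")
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        clean.append((a, b, rest[0] if rest else "interacts"))
    if not clean:
        raise NetworkError("network has no edges (m = 0), modularity undefined")
    return TransOmicNetwork(list(layers), layers, clean)


def modularity_matrix(net: TransOmicNetwork) -> np.ndarray:
    """Return the modularity matrix B of the network (requires m >= 1)."""
    return net.B.copy()


def shift_negative_definite(B: np.ndarray) -> tuple[np.ndarray, float]:
    """Shift a symmetric matrix to negative semidefiniteness.

    Returns ``(B - lambda_B * I, lambda_B)`` where ``lambda_B`` is the
    largest absolute eigenvalue of ``B``.  All eigenvalues of the result
    are <= 0 (up to numerical tolerance).
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise NetworkError("B must be a square matrix")
    if B.size and np.max(np.abs(B - B.T)) > 1e-10:
        raise NetworkError("B must be symmetric (asymmetry beyond 1e-10)")
    if B.size == 0:
        return B.copy(), 0.0
    eig = np.linalg.eigvalsh(B)
    lambda_b = float(np.max(np.abs(eig)))
    return B - lambda_b * np.eye(B.shape[0]), lambda_b


def induced_components(
    net: TransOmicNetwork,
    selected: Iterable[str],
    min_size: int = 5,
) -> list[SubnetworkComponent]:
    """Connected components of the prior graph induced on ``selected`` nodes.

    Only components with at least ``min_size`` nodes are returned, ordered by
    size descending with ties broken by smallest node identifier.
    """
    selected = set(selected)
    if min_size < 1:
        raise NetworkError("min_size must be >= 1")
    unknown = sorted(selected - set(net.node_ids))
    if unknown:
        raise NetworkError(f"selected nodes absent from network: {unknown}")
    sub = net.graph.subgraph(selected)
    comps = []
    for comp in nx.connected_components(sub):
        if len(comp) < min_size:
            continue
        nodes = tuple(sorted(comp))
        edges = tuple(sorted(tuple(sorted(e)) for e in sub.subgraph(comp).edges))
        comps.append(SubnetworkComponent(nodes=nodes, edges=edges))
    comps.sort(key=lambda c: (-c.size, c.nodes[0]))
    return comps


def centralities(component: SubnetworkComponent | nx.Graph) -> pd.DataFrame:
    """Shortest-path centralities of a connected component.

    Returns a DataFrame indexed by node with columns ``degree``,
    ``avg_shortest_path``, ``betweenness`` (normalized by (n-1)(n-2)/2,
    zero for n < 3) and ``closeness`` (reciprocal of the average
    shortest-path length).
    """
    g = component.to_graph() if isinstance(component, SubnetworkComponent) else component
    n = g.number_of_nodes()
    if n < 2:
        raise NetworkError("centralities need a component with >= 2 nodes")
    if not nx.is_connected(g):
        raise NetworkError("centralities require a connected component")
    spl = dict(nx.all_pairs_shortest_path_length(g))
    rows = {}
    btw = nx.betweenness_centrality(g, normalized=True)
    for v in sorted(g.nodes):
        avg = sum(spl[v].values()) / (n - 1)
        rows[v] = {
            "degree": g.degree[v],
            "avg_shortest_path": avg,
            "betweenness": btw[v],
            "closeness": 1.0 / avg,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("node")


def rank_by_centrality(table: pd.DataFrame, metric: str, ascending: bool = False) -> list[str]:
    """Node ranking by one centrality metric; ties broken by node ID."""
    if metric not in table.columns:
        raise NetworkError(f"unknown centrality metric {metric!r}")
    key = table[metric]
    order = sorted(table.index, key=lambda v: (key[v] if ascending else -key[v], v))
    return order


def subsampling_centrality_threshold(
    net: TransOmicNetwork,
    k: int,
    reps: int,
    statistic: str = "mean",
    seed: int = 0,
) -> dict[str, float]:
    """Null centrality cut-offs from random feature subsets.

    Repeatedly draws ``k`` nodes uniformly without replacement, maps them to
    the prior network, computes centralities on the induced components
    (singleton nodes contribute degree 0, betweenness 0, closeness 0), and
    returns the requested statistic (``mean`` or ``q25``, the 25th
    percentile) of the pooled per-node values for each metric.
    """
    if not 1 <= k <= net.p:
        raise NetworkError(f"k must be in [1, {net.p}], got {k}")
    if reps < 1:
        raise NetworkError("reps must be >= 1")
    if statistic not in ("mean", "q25"):
        raise NetworkError("statistic must be 'mean' or 'q25'")
    rng = np.random.default_rng(seed)
    pool: dict[str, list[float]] = {
        "degree": [], "avg_shortest_path": [], "betweenness": [], "closeness": []
    }
    for _ in range(reps):
        sample = rng.choice(net.node_ids, size=k, replace=False)
        comps = induced_components(net, sample, min_size=1)
        for comp in comps:
            if comp.size == 1:
                pool["degree"].append(0.0)
                pool["betweenness"].append(0.0)
                pool["closeness"].append(0.0)
                pool["avg_shortest_path"].append(np.nan)
            else:
                tab = centralities(comp)
                pool["degree"].extend(tab["degree"].tolist())
                pool["betweenness"].extend(tab["betweenness"].tolist())
                pool["closeness"].extend(tab["closeness"].tolist())
                pool["avg_shortest_path"].extend(tab["avg_shortest_path"].tolist())
    out = {}
    for metric, values in pool.items():
        arr = np.asarray(values, dtype=float)
        if statistic == "mean":
            out[metric] = float(np.nanmean(arr)) if np.any(~np.isnan(arr)) else np.nan
        else:
            out[metric] = float(np.nanpercentile(arr, 25)) if np.any(~np.isnan(arr)) else np.nan
    return out
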