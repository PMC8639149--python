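"""Patient similarity network: construction, clustering, attribute mapping.

The network is the unweighted union-symmetrized k-NN graph of patients in
the embedded space, with k the smallest value giving a fully connected
graph.  Clustering uses walktrap (Pons-Latapy), a *deterministic*
agglomerative method: its "random steps" parameter t is the length of the
random walks whose transition-probability profiles define community
distance — nothing is sampled, so no seed is involved.  The walk length
is chosen by scanning t = 1..100 and keeping the first t whose
max-modularity dendrogram cut attains the global maximum modularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .embedding import build_nng, minimal_connected_k

__all__ = [
    "PatientNetwork",
    "AssortativityResult",
    "knn_adjacency",
    "walktrap_dendrogram",
    "max_modularity_cut",
    "modularity",
    "select_walk_length",
    "contract_clusters",
    "assortativity_numeric",
]


@dataclass
class PatientNetwork:
    """Adjacency plus (optionally) the walktrap clustering attached to it."""

    ids: list
    graph: nx.Graph  # unweighted, connected
    k_used: int
    cluster_labels: dict | None = None  # id -> cluster index
    modularity_q: float | None = None
    t_used: int | None = None
    contracted: nx.Graph | None = None

    @property
    def n_clusters(self) -> int:
        if self.cluster_labels is None:
            raise ValueError("network not clustered yet")
        return len(set(self.cluster_labels.values()))


@dataclass
class AssortativityResult:
    attribute: str
    ar: float | None  # None when undefined (zero variance over edge ends)


def knn_adjacency(coords: np.ndarray, ids: list | None = None, k: int | None = None) -> PatientNetwork:
    """Unweighted k-NN similarity network over embedded coordinates.

    When ``k`` is omitted, the smallest k producing a connected
    union-symmetrized graph is used (and recorded as ``k_used``).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 2:
        raise ValueError("need at least two points")
    ids = list(ids) if ids is not None else list(range(len(coords)))
    D = squareform(pdist(coords))
    if k is None:
        k = minimal_connected_k(D)
    g = build_nng(D, k)
    if not nx.is_connected(g):
        raise ValueError(f"k={k} gives a disconnected graph")
    unweighted = nx.Graph()
    unweighted.add_nodes_from(g.nodes)
    unweighted.add_edges_from(g.edges)
    return PatientNetwork(ids=ids, graph=unweighted, k_used=k)


def _to_igraph(graph: nx.Graph) -> ig.Graph:
    nodes = sorted(graph.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    return ig.Graph(
        n=len(nodes), edges=[(index[u], index[v]) for u, v in graph.edges]
    )


def walktrap_dendrogram(graph: nx.Graph, t: int) -> ig.VertexDendrogram:
    """Walktrap merge dendrogram for walk length t (deterministic)."""
    if t < 1:
        raise ValueError("walk length t must be >= 1")
    if not nx.is_connected(graph):
        raise ValueError("walktrap requires a connected graph")
    return _to_igraph(graph).community_walktrap(steps=t)


def max_modularity_cut(graph: nx.Graph, dendrogram: ig.VertexDendrogram) -> tuple[dict, float]:
    """Cut the dendrogram at its max-modularity level.

    Returns labels keyed by node (in sorted node order) and the modularity
    of that partition computed with :func:`modularity`.
    """
    clustering = dendrogram.as_clustering()
    nodes = sorted(graph.nodes)
    labels = {u: int(c) for u, c in zip(nodes, clustering.membership)}
    return labels, modularity(graph, labels)


def modularity(graph: nx.Graph, partition: dict) -> float:
    """Newman modularity Q = sum_c (e_cc - a_c^2) from direct edge counts."""
    if set(partition) != set(graph.nodes):
        raise ValueError("partition must cover exactly the graph's nodes")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    communities = set(partition.values())
    within = dict.fromkeys(communities, 0)
    ends = dict.fromkeys(communities, 0)
    for u, v in graph.edges:
        cu, cv = partition[u], partition[v]
        if cu == cv:
            within[cu] += 1
        ends[cu] += 1
        ends[cv] += 1
    return float(
        sum(within[c] / m - (ends[c] / (2 * m)) ** 2 for c in communities)
    )


def select_walk_length(
    graph: nx.Graph, t_range: range = range(1, 101), tol: float = 1e-12
) -> tuple[int, dict, float]:
    """First walk length whose best cut attains the global max modularity.

    Every t in ``t_range`` gets its own dendrogram and max-modularity cut;
    the smallest t within ``tol`` of the best Q wins.  Returns
    (t*, labels, Q*).
    """
    results = {}
    for t in t_range:
        labels, q = max_modularity_cut(graph, walktrap_dendrogram(graph, t))
        results[t] = (labels, q)
    q_max = max(q for _, q in results.values())
    for t in t_range:
        labels, q = results[t]
        if q >= q_max - tol:
            return t, labels, q
    raise AssertionError("unreachable")


def cluster_network(network: PatientNetwork, t_range: range = range(1, 101)) -> PatientNetwork:
    """Attach the walk-length-selected walktrap clustering to the network."""
    t, labels, q = select_walk_length(network.graph, t_range)
    network.t_used = t
    network.cluster_labels = {network.ids[u]: c for u, c in labels.items()}
    network.modularity_q = q
    return network


def contract_clusters(
    network: PatientNetwork, attributes: pd.DataFrame | None = None
) -> nx.Graph:
    """Collapse the network to one node per cluster.

    Cluster nodes are linked iff at least one patient edge crosses between
    them.  When ``attributes`` (indexed by patient id) is given, numeric
    columns are averaged per cluster and stored as node attributes, along
    with the member count.
    """
    if network.cluster_labels is None:
        raise ValueError("cluster the network first")
    label_of = {u: network.cluster_labels[network.ids[u]] for u in network.graph.nodes}
    cg = nx.Graph()
    cg.add_nodes_from(set(label_of.values()))
    for u, v in network.graph.edges:
        if label_of[u] != label_of[v]:
            cg.add_edge(label_of[u], label_of[v])
    members = {}
    for pid, c in network.cluster_labels.items():
        members.setdefault(c, []).append(pid)
    for c in cg.nodes:
        cg.nodes[c]["n_members"] = len(members[c])
        if attributes is not None:
            sub = attributes.loc[members[c]]
            for col in sub.select_dtypes("number").columns:
                cg.nodes[c][f"mean_{col}"] = float(sub[col].mean())
    network.contracted = cg
    return cg


def assortativity_numeric(graph: nx.Graph, attribute: dict) -> AssortativityResult:
    """Numeric assortativity: Pearson r of the attribute over edge ends.

    Every edge contributes both orientations, matching Newman's
    definition.  Zero variance across edge ends makes the coefficient
    undefined, reported as ``ar=None``.
    """
    missing = [u for u in graph.nodes if u not in attribute]
    if missing:
        raise ValueError(f"attribute missing for nodes {missing[:5]}")
    x, y = [], []
    for u, v in graph.edges:
        x.extend((attribute[u], attribute[v]))
        y.extend((attribute[v], attribute[u]))
    x, y = np.asarray(x, float), np.asarray(y, float)
    name = getattr(attribute, "name", "attribute")
    if x.std() == 0 or y.std() == 0:
        return AssortativityResult(name, None)
    r = float(np.corrcoef(x, y)[0, 1])
    if math.isnan(r):
        return AssortativityResult(name, None)
    return AssortativityResult(name, r)
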