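"""Patient distances, Isomap embedding, and topology-guided (k, d) selection.

Isomap is run as its three classical steps — k-nearest-neighbour graph,
graph geodesics, classical MDS — so every intermediate (the geodesic
matrix, the eigenvalues, the per-dimension residual variance) stays
inspectable.  Candidate embeddings are scored by how well they preserve
the persistent homology of the geodesic matrix: the 2-Wasserstein
distances between the input diagrams and the embedded-space diagrams in
dimensions 0 and 1 (WD0, WD1), following the residual-variance elbow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .datatypes import CdfFeatureMatrix
from .persistence import PersistenceDiagram, rips_persistence, wasserstein_distance

__all__ = [
    "EmbeddingSolution",
    "pairwise_euclidean",
    "build_nng",
    "geodesic_distances",
    "classical_mds",
    "residual_variance",
    "select_embedding",
]


@dataclass
class EmbeddingSolution:
    """A selected Isomap solution plus the diagnostics behind the choice."""

    ids: list
    k: int
    k_min: int
    coords: np.ndarray  # patients x d_max, ordered by eigenvalue
    eigenvalues: np.ndarray
    geodesic: np.ndarray
    rv_by_d: dict[int, float]
    diagrams_input: dict[int, PersistenceDiagram]
    wd0_by_d: dict[int, float]
    wd1_by_d: dict[int, float]
    selected_d: int
    elbow_d: int
    candidate_scores: dict[int, float] = field(default_factory=dict)

    @property
    def selected_coords(self) -> np.ndarray:
        return self.coords[:, : self.selected_d]


def pairwise_euclidean(features: CdfFeatureMatrix | np.ndarray) -> np.ndarray:
    """Euclidean distance between every pair of patients' feature vectors."""
    X = features.values if isinstance(features, CdfFeatureMatrix) else np.asarray(features)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    return squareform(pdist(X))


def build_nng(D: np.ndarray, k: int) -> nx.Graph:
    """Union-symmetrized k-nearest-neighbour graph weighted by distance.

    Edge (i, j) exists iff j is among i's k nearest neighbours or vice
    versa; distance ties are broken toward the smaller index.
    """
    n = len(D)
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < n")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, D[i]))
        neighbors = [j for j in order if j != i][:k]
        for j in neighbors:
            g.add_edge(i, int(j), weight=float(D[i, j]))
    return g


def _adjacency_connected(D: np.ndarray, k: int) -> bool:
    n = len(D)
    order = np.argsort(D, axis=1, kind="stable")
    A = np.zeros((n, n), dtype=bool)
    for i in range(n):
        nbrs = [j for j in order[i] if j != i][:k]
        A[i, nbrs] = True
    A |= A.T
    return connected_components(A, directed=False)[0] == 1


def minimal_connected_k(D: np.ndarray) -> int:
    """Smallest k whose union-symmetrized k-NNG is connected."""
    n = len(D)
    for k in range(1, n):
        if _adjacency_connected(D, k):
            return k
    raise ValueError("no connected k-NNG below k = n - 1")


def geodesic_distances(graph: nx.Graph) -> np.ndarray:
    """All-pairs shortest-path distances on the weighted graph."""
    n = graph.number_of_nodes()
    W = np.zeros((n, n))
    for u, v, d in graph.edges(data="weight"):
        W[u, v] = W[v, u] = d
    ncomp, _ = connected_components(W != 0, directed=False)
    if ncomp > 1:
        raise ValueError(f"graph has {ncomp} components; geodesics undefined")
    return shortest_path(W, method="D", directed=False)


def classical_mds(D: np.ndarray, d_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers -D^2/2, keeps the top positive eigenvalues, and scales
    eigenvectors by sqrt(eigenvalue).  Coordinate signs are fixed by
    forcing the largest-magnitude loading of each axis positive so runs
    are reproducible across eigensolvers.
    """
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(vals.max(), 1.0)
    n_pos = int(pos.sum())
    if d_max > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating d_max from {d_max}"
        )
        d_max = n_pos
    vals, vecs = vals[:d_max], vecs[:, :d_max]
    coords = vecs * np.sqrt(vals)
    for a in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, a]))
        if coords[j, a] < 0:
            coords[:, a] = -coords[:, a]
    return coords, vals


def residual_variance(D_input: np.ndarray, D_embedded: np.ndarray) -> float:
    """1 - R^2 between input and embedded pairwise distances."""
    if D_input.shape != D_embedded.shape:
        raise ValueError("matrices must share a shape")
    iu = np.triu_indices(len(D_input), k=1)
    x, y = D_input[iu], D_embedded[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a distance matrix")
    r, _ = pearsonr(x, y)
    return float(1.0 - r * r)


def _embedding_diagnostics(
    D: np.ndarray, k: int, d_values: range
) -> tuple[np.ndarray, np.ndarray, dict, dict, dict, np.ndarray, dict]:
    Dm = geodesic_distances(build_nng(D, k))
    coords, vals = classical_mds(Dm, d_values.stop - 1)
    diagrams_in = rips_persistence(Dm)
    rv, wd0, wd1 = {}, {}, {}
    for d in d_values:
        if d > coords.shape[1]:
            break
        Dy = squareform(pdist(coords[:, :d]))
        rv[d] = residual_variance(Dm, Dy)
        diagrams_d = rips_persistence(Dy)
        wd0[d] = wasserstein_distance(diagrams_in[0], diagrams_d[0])
        wd1[d] = wasserstein_distance(diagrams_in[1], diagrams_d[1])
    return Dm, coords, rv, wd0, wd1, vals, diagrams_in


def _elbow(rv_by_d: dict[int, float]) -> int:
    """Dimension at the residual-variance elbow (max second difference)."""
    ds = sorted(rv_by_d)
    if len(ds) < 3:
        return ds[0]
    best_d, best_curv = ds[1], -np.inf
    for a, b, c in zip(ds, ds[1:], ds[2:]):
        curv = rv_by_d[a] - 2 * rv_by_d[b] + rv_by_d[c]
        if curv > best_curv:
            best_curv, best_d = curv, b
    return best_d


def select_embedding(
    D: np.ndarray,
    ids: list | None = None,
    d_max: int = 10,
    n_k_candidates: int = 5,
    wd_rtol: float = 0.01,
) -> EmbeddingSolution:
    """Choose the neighbour count k and dimensionality d for Isomap.

    k_min is the smallest k giving a connected graph; k candidates are
    k_min .. k_min + n_k_candidates - 1.  For each (k, d) the residual
    variance and the Wasserstein distances WD0/WD1 between the geodesic
    and embedded diagrams are computed.  The selected k minimizes
    WD0 + WD1 summed over candidate d (ties to the smaller k); at that k,
    d is the smallest dimension at or beyond the residual-variance elbow
    whose WD0 is within ``wd_rtol`` of the minimum (adding dimensions
    that only shave a sliver off WD0 is not worth the extra coordinates).
    """
    n = len(D)
    if n < 10:
        raise ValueError("need at least 10 patients to select an embedding")
    ids = list(ids) if ids is not None else list(range(n))
    d_max = min(d_max, n - 1)
    d_values = range(1, d_max + 1)
    k_min = minimal_connected_k(D)
    candidates = [k for k in range(k_min, k_min + n_k_candidates) if k < n]

    per_k = {}
    scores = {}
    for k in candidates:
        per_k[k] = _embedding_diagnostics(D, k, d_values)
        _, _, _, wd0, wd1, _, _ = per_k[k]
        scores[k] = float(sum(wd0.values()) + sum(wd1.values()))
    best_k = min(candidates, key=lambda k: (scores[k], k))
    Dm, coords, rv, wd0, wd1, vals, diagrams_in = per_k[best_k]
    elbow_d = _elbow(rv)
    eligible = sorted(d for d in wd0 if d >= elbow_d) or sorted(wd0)
    wd0_min = min(wd0[d] for d in eligible)
    best_d = next(d for d in eligible if wd0[d] <= wd0_min * (1 + wd_rtol) + 1e-12)
    return EmbeddingSolution(
        ids=ids,
        k=best_k,
        k_min=k_min,
        coords=coords,
        eigenvalues=vals,
        geodesic=Dm,
        rv_by_d=rv,
        diagrams_input=diagrams_in,
        wd0_by_d=wd0,
        wd1_by_d=wd1,
        selected_d=best_d,
        elbow_d=elbow_d,
        candidate_scores=scores,
    )
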