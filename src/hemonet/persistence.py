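"""Vietoris-Rips persistent homology and Wasserstein diagram distances.

Persistence is computed directly from a distance matrix.  Dimension 0
(connected components) comes from the minimum spanning tree; dimension 1
(loops) from standard Z/2 boundary-matrix reduction of the triangle
boundary operator, with columns stored as integer bitmasks so the XOR
column additions are cheap.

The filtration is truncated at the *enclosing radius* — the smallest r
such that some point lies within r of every other.  At that radius the
complex is a cone (hence contractible), so every 1-dimensional class has
died and exactly one 0-dimensional class survives; that essential class
is recorded with its death capped at the enclosing radius so diagram
distances stay finite and comparable across matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse.csgraph import minimum_spanning_tree

__all__ = ["PersistenceDiagram", "rips_persistence", "wasserstein_distance"]


@dataclass
class PersistenceDiagram:
    """Multiset of (birth, death) pairs for one homological dimension."""

    dimension: int
    pairs: np.ndarray  # (n, 2), death >= birth

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        if len(self.pairs) and np.any(self.pairs[:, 1] < self.pairs[:, 0]):
            raise ValueError("death must be >= birth")

    def __len__(self) -> int:
        return len(self.pairs)


def enclosing_radius(D: np.ndarray) -> float:
    """Smallest r with a point within r of all others (filtration cap)."""
    return float(np.min(np.max(D, axis=1)))


def _h0_pairs(D: np.ndarray, cap: float) -> np.ndarray:
    n = len(D)
    if n == 1:
        return np.array([[0.0, cap]])
    mst = minimum_spanning_tree(D).tocoo()
    deaths = np.sort(mst.data)
    pairs = np.column_stack([np.zeros(n), np.concatenate([deaths, [cap]])])
    return pairs


def _h1_pairs(D: np.ndarray, threshold: float) -> np.ndarray:
    n = len(D)
    if n < 3:
        return np.empty((0, 2))
    iu, ju = np.triu_indices(n, k=1)
    lengths = D[iu, ju]
    keep = lengths <= threshold
    iu, ju, lengths = iu[keep], ju[keep], lengths[keep]
    # rank edges by (length, i, j); bit position in column masks = rank
    order = np.lexsort((ju, iu, lengths))
    edge_rank = {}
    edge_len = np.empty(len(order))
    for r, e in enumerate(order):
        edge_rank[(int(iu[e]), int(ju[e]))] = r
        edge_len[r] = lengths[e]

    tri = [
        (i, j, k)
        for i, j, k in itertools.combinations(range(n), 3)
        if (i, j) in edge_rank and (i, k) in edge_rank and (j, k) in edge_rank
    ]
    if not tri:
        return np.empty((0, 2))
    tri_arr = np.array(tri)
    diam = np.maximum.reduce(
        [
            D[tri_arr[:, 0], tri_arr[:, 1]],
            D[tri_arr[:, 0], tri_arr[:, 2]],
            D[tri_arr[:, 1], tri_arr[:, 2]],
        ]
    )
    tri_order = np.lexsort((tri_arr[:, 2], tri_arr[:, 1], tri_arr[:, 0], diam))

    pivot_of: dict[int, int] = {}  # low edge rank -> reduced column bitmask
    pairs = []
    for t in tri_order:
        i, j, k = map(int, tri_arr[t])
        col = (
            (1 << edge_rank[(i, j)])
            | (1 << edge_rank[(i, k)])
            | (1 << edge_rank[(j, k)])
        )
        while col:
            low = col.bit_length() - 1
            other = pivot_of.get(low)
            if other is None:
                pivot_of[low] = col
                birth, death = edge_len[low], diam[t]
                if death > birth:
                    pairs.append((birth, death))
                break
            col ^= other
    return np.array(pairs) if pairs else np.empty((0, 2))


def rips_persistence(D: np.ndarray, max_dim: int = 1) -> dict[int, PersistenceDiagram]:
    """Persistence diagrams (dims 0..max_dim) of the Rips filtration of D."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square distance matrix")
    cap = enclosing_radius(D) if len(D) > 1 else 0.0
    out = {0: PersistenceDiagram(0, _h0_pairs(D, cap))}
    if max_dim >= 1:
        out[1] = PersistenceDiagram(1, _h1_pairs(D, cap))
    return out


def wasserstein_distance(
    A: PersistenceDiagram, B: PersistenceDiagram, power: float = 2.0
) -> float:
    """q-Wasserstein distance between two diagrams (L2 ground metric).

    Unmatched points may be transported to their orthogonal projection on
    the diagonal; the optimal partial matching is solved exactly as an
    assignment problem on the diagonally-augmented cost matrix.
    """
    if A.dimension != B.dimension:
        raise ValueError("diagrams must share a homological dimension")
    a, b = A.pairs, B.pairs
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 0.0
    diag_a = (a[:, 1] - a[:, 0]) / np.sqrt(2.0) if n else np.empty(0)
    diag_b = (b[:, 1] - b[:, 0]) / np.sqrt(2.0) if m else np.empty(0)
    big = (
        float(np.sum(diag_a**power) + np.sum(diag_b**power)) + 1.0
    )  # upper bound on any useful entry
    C = np.full((n + m, n + m), big)
    if n and m:
        diff = a[:, None, :] - b[None, :, :]
        C[:n, :m] = np.sqrt((diff**2).sum(axis=2)) ** power
    C[np.arange(n), m + np.arange(n)] = diag_a**power
    C[n + np.arange(m), np.arange(m)] = diag_b**power
    C[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(C)
    return float(C[rows, cols].sum() ** (1.0 / power))
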