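"""Spatial neighborhood graph construction.

The spatial branch operates on a binary symmetric K-nearest-neighbor
adjacency built from Euclidean distances between spot coordinates, plus
the symmetrically normalized propagation operator used by the graph
convolutions.  Self-loops appear only in the propagation operator; the
adjacency itself keeps a zero diagonal because it doubles as the
reconstruction target of the graph auto-encoder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class SpatialGraph:
    A: np.ndarray                 # binary symmetric adjacency, zero diagonal
    A_norm: np.ndarray            # D^{-1/2} (A + I) D^{-1/2}
    K: int
    neighbor_sets: List[np.ndarray] = field(default_factory=list)

    @property
    def n_spots(self) -> int:
        return self.A.shape[0]

    def neighbor_mean_operator(self) -> np.ndarray:
        """Row-stochastic operator averaging over each spot's neighbors."""
        deg = self.A.sum(axis=1, keepdims=True)
        deg[deg == 0] = 1.0
        return self.A / deg

    def to_edgelist(self, path) -> None:
        """Write undirected edges (i < j) as a two-column TSV."""
        ii, jj = np.nonzero(np.triu(self.A, k=1))
        with open(Path(path), "w") as fh:
            fh.write("i\tj\n")
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\n")


def build_knn_adjacency(coords: np.ndarray, K: int) -> SpatialGraph:
    """Binary symmetric KNN graph over spot coordinates.

    ``A[i, j] = A[j, i] = 1`` iff j is among the K Euclidean-nearest
    neighbors of i, or vice versa (mutualization can only add edges, so
    each spot ends up with between K and N-1 neighbors).  Distance ties
    at the K-th neighbor are broken by lower spot index for determinism.
    """
    coords = np.asarray(coords, dtype=float)
    N = coords.shape[0]
    if not (1 <= K <= N - 1):
        raise ValueError(f"K must satisfy 1 <= K <= N-1 (K={K}, N={N})")

    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] < N:
        logger.warning("duplicate coordinates present (%d unique of %d spots)",
                       uniq.shape[0], N)

    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    # stable argsort: equal distances resolve to the lower column index
    order = np.argsort(D, axis=1, kind="stable")[:, :K]
    directed = np.zeros((N, N), dtype=float)
    directed[np.repeat(np.arange(N), K), order.ravel()] = 1.0
    A = np.maximum(directed, directed.T)
    np.fill_diagonal(A, 0.0)

    neighbor_sets = [np.flatnonzero(A[i]) for i in range(N)]
    return SpatialGraph(A=A, A_norm=normalize_adjacency(A), K=K,
                        neighbor_sets=neighbor_sets)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN propagation operator ``D~^{-1/2} (A+I) D~^{-1/2}``.

    ``D~`` is the degree matrix of ``A + I``; an isolated node reduces
    to a pure self-loop of weight 1.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    At = A + np.eye(A.shape[0])
    dinv_sqrt = 1.0 / np.sqrt(At.sum(axis=1))
    return At * dinv_sqrt[:, None] * dinv_sqrt[None, :]
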