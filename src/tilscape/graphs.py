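"""k-nearest-neighbour spatial graphs over patch point patterns."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

DEFAULT_K = 6


@dataclass
class SpatialGraph:
    """Undirected k-NN graph over a set of points.

    Edges are the symmetrised union of each point's ``k`` Euclidean nearest
    neighbours; weights are 1 for neighbours and 0 otherwise.  No self-loops.
    """

    coords: np.ndarray
    adjacency: sp.csr_matrix  # symmetric 0/1, zero diagonal
    k: int

    _nx_cache: Optional[nx.Graph] = None

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def to_networkx(self) -> nx.Graph:
        if self._nx_cache is None:
            g = nx.from_scipy_sparse_array(self.adjacency)
            self._nx_cache = g
        return self._nx_cache


def knn_graph(coords: np.ndarray, k: int = DEFAULT_K) -> SpatialGraph:
    """Build the symmetrised k-NN graph for ``coords`` ((n, 2) array)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        adj = sp.csr_matrix((n, n))
        return SpatialGraph(coords=coords, adjacency=adj, k=k)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    adj = nn.kneighbors_graph(coords, mode="connectivity")
    adj.setdiag(0)
    adj.eliminate_zeros()
    adj = adj.maximum(adj.T)  # undirected union
    adj.data[:] = 1.0
    return SpatialGraph(coords=coords, adjacency=adj.tocsr(), k=k)


def grid_rook_graph(shape) -> SpatialGraph:
    """4-neighbour (rook) adjacency over an h x w grid of patch centres.

    Mainly useful for validating spatial autocorrelation against classical
    lattice results (a 0/1 checkerboard has Moran's I of exactly -1).
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    idx = np.arange(h * w).reshape(h, w)
    pairs = []
    if w > 1:
        pairs.append(np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()]))
    if h > 1:
        pairs.append(np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()]))
    edges = np.vstack(pairs)
    data = np.ones(len(edges))
    adj = sp.coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(h * w, h * w))
    adj = (adj + adj.T).tocsr()
    adj.data[:] = 1.0
    return SpatialGraph(coords=coords, adjacency=adj, k=4)
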