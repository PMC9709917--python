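"""Weighted k-NN graphs over HEALPix pixels and their combinatorial Laplacians.

Pixels are graph vertices; each connects to its ``k`` nearest pixels by
chordal (3D) distance with Gaussian weights ``w_ij = exp(-|x_i - x_j|^2 / 4t)``
and the adjacency is union-symmetrized.  When not given, the kernel width
``t`` defaults to one quarter of the mean squared distance to the k-th
neighbor, following the DeepSphere construction.  The combinatorial Laplacian
is ``L = D - W``; polynomial filters in ``L`` implement localized spherical
convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .healpix import PixelGrid, healpix_sampling

__all__ = ["SphereGraph", "build_graph", "build_graph_hierarchy"]


@dataclass
class SphereGraph:
    n_side: int
    adjacency: sp.csr_matrix   # symmetric, zero diagonal, nonnegative
    laplacian: sp.csr_matrix   # L = D - W, PSD, zero row sums
    kernel_width: float
    _lmax: float | None = None

    @property
    def n_pix(self) -> int:
        return self.adjacency.shape[0]

    @property
    def lmax(self) -> float:
        """Largest Laplacian eigenvalue (deterministic Lanczos; falls back to
        the 2*max-degree bound)."""
        if self._lmax is None:
            try:
                v0 = np.ones(self.n_pix) + 1e-3 * np.arange(self.n_pix)
                self._lmax = float(sp.linalg.eigsh(
                    self.laplacian, k=1, which="LM", v0=v0,
                    return_eigenvectors=False)[0])
            except Exception:
                self._lmax = float(2.0 * self.laplacian.diagonal().max())
        return self._lmax


def build_graph(grid: PixelGrid, k: int = 20, t: float | None = None) -> SphereGraph:
    """k-NN Gaussian-weighted graph on the pixel grid.

    ``k`` is clipped to ``n_pix - 1`` at the coarsest resolutions.
    """
    n = grid.n_pix
    if k >= n:
        raise ValueError(f"k={k} must be < n_pix={n}")
    k_eff = min(k, n - 1)
    tree = cKDTree(grid.unit_vectors)
    dist, idx = tree.query(grid.unit_vectors, k=k_eff + 1)  # includes self
    dist, idx = dist[:, 1:], idx[:, 1:]

    if t is None:
        t = float(np.mean(dist[:, -1] ** 2) / 4.0)
    w = np.exp(-(dist**2) / (4.0 * t))

    rows = np.repeat(np.arange(n), k_eff)
    W = sp.coo_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n)).tocsr()
    W = W.maximum(W.T)          # union-symmetrize
    W.setdiag(0.0)
    W.eliminate_zeros()

    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    return SphereGraph(n_side=grid.n_side, adjacency=W,
                       laplacian=L.tocsr(), kernel_width=t)


def build_graph_hierarchy(n_side: int, depth: int, k: int = 20,
                          t: float | None = None) -> list[SphereGraph]:
    """Graphs at ``n_side, n_side/2, ..." for ``depth`` pooled resolutions.

    Each level is rebuilt independently with the same ``k`` (clipped near the
    base resolution).
    """
    graphs = []
    ns = n_side
    for _ in range(depth):
        if ns < 1:
            raise ValueError("hierarchy deeper than the pixelization allows")
        graphs.append(build_graph(healpix_sampling(ns), k=k, t=t))
        ns //= 2
    return graphs
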