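"""Nested HEALPix pixelization of the unit sphere.

HEALPix (Hierarchical Equal Area isoLatitude Pixelization) subdivides the
twelve faces of a rhombic dodecahedron projection of the sphere into
``n_side**2`` equal-area pixels each, for ``n_pix = 12 * n_side**2`` pixels in
total.  Only the *nested* ordering is provided: the four children of pixel
``p`` at resolution ``n_side`` are pixels ``4p .. 4p+3`` at resolution
``2*n_side``, which is what makes hierarchical 4:1 pooling a simple reshape.

The pixel-index <-> angle transforms follow the canonical HEALPix scheme
(Gorski et al.); pixel centers at ``n_side=1`` are the analytically known
twelve base-pixel centers (four at z = 2/3, four on the equator, four at
z = -2/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["PixelGrid", "healpix_sampling", "pix2vec_nest", "vec2pix_nest", "n_pix_of"]

# rows: base face 0..11; starting ring / starting azimuth factors of each face
_JRLL = np.array([2, 2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 4])
_JPLL = np.array([1, 3, 5, 7, 0, 2, 4, 6, 1, 3, 5, 7])


def _check_n_side(n_side: int) -> int:
    n_side = int(n_side)
    if n_side < 1 or (n_side & (n_side - 1)) != 0:
        raise ValueError(f"n_side must be a power of two >= 1, got {n_side}")
    return n_side


def n_pix_of(n_side: int) -> int:
    """Number of pixels at resolution ``n_side``: 12 * n_side**2."""
    return 12 * _check_n_side(n_side) ** 2


def _compress_bits(v: np.ndarray) -> np.ndarray:
    """Extract the even-position bits of ``v`` (inverse of bit interleaving)."""
    v = v & 0x5555555555555555
    v = (v | (v >> 1)) & 0x3333333333333333
    v = (v | (v >> 2)) & 0x0F0F0F0F0F0F0F0F
    v = (v | (v >> 4)) & 0x00FF00FF00FF00FF
    v = (v | (v >> 8)) & 0x0000FFFF0000FFFF
    v = (v | (v >> 16)) & 0x00000000FFFFFFFF
    return v


def _spread_bits(v: np.ndarray) -> np.ndarray:
    """Spread bits of ``v`` to even positions (for bit interleaving)."""
    v = v & 0x00000000FFFFFFFF
    v = (v | (v << 16)) & 0x0000FFFF0000FFFF
    v = (v | (v << 8)) & 0x00FF00FF00FF00FF
    v = (v | (v << 4)) & 0x0F0F0F0F0F0F0F0F
    v = (v | (v << 2)) & 0x3333333333333333
    v = (v | (v << 1)) & 0x5555555555555555
    return v


def _nest2xyf(n_side: int, p: np.ndarray):
    npface = n_side * n_side
    face = p // npface
    pf = p % npface
    ix = _compress_bits(pf)
    iy = _compress_bits(pf >> 1)
    return ix, iy, face


def _xyf2nest(n_side: int, ix, iy, face):
    return face * (n_side * n_side) + _spread_bits(ix) + (_spread_bits(iy) << 1)


def _nest2ang(n_side: int, p: np.ndarray):
    """Nested pixel index -> (z = cos(theta), phi) of the pixel center."""
    ix, iy, face = _nest2xyf(n_side, p)
    jr = _JRLL[face] * n_side - ix - iy - 1  # ring index, 1 .. 4*n_side-1

    z = np.empty(p.shape, dtype=float)
    nr = np.empty(p.shape, dtype=np.int64)
    kshift = np.zeros(p.shape, dtype=np.int64)

    north = jr < n_side
    south = jr > 3 * n_side
    eq = ~(north | south)

    nr[north] = jr[north]
    z[north] = 1.0 - nr[north] ** 2 / (3.0 * n_side**2)

    nr[south] = 4 * n_side - jr[south]
    z[south] = -1.0 + nr[south] ** 2 / (3.0 * n_side**2)

    nr[eq] = n_side
    z[eq] = (2 * n_side - jr[eq]) * 2.0 / (3.0 * n_side)
    kshift[eq] = (jr[eq] - n_side) & 1

    jp = (_JPLL[face] * nr + ix - iy + 1 + kshift) // 2
    jp = np.where(jp > 4 * nr, jp - 4 * nr, jp)
    jp = np.where(jp < 1, jp + 4 * nr, jp)

    phi = (jp - (kshift + 1) * 0.5) * (np.pi / (2.0 * nr))
    return z, phi


def pix2vec_nest(n_side: int, ipix=None) -> np.ndarray:
    """Unit vectors of nested-ordered pixel centers.

    Parameters
    ----------
    n_side : power-of-two resolution parameter.
    ipix : optional pixel indices; defaults to all ``12*n_side**2`` pixels.
    """
    n_side = _check_n_side(n_side)
    if ipix is None:
        ipix = np.arange(n_pix_of(n_side), dtype=np.int64)
    ipix = np.asarray(ipix, dtype=np.int64)
    z, phi = _nest2ang(n_side, ipix)
    st = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([st * np.cos(phi), st * np.sin(phi), z], axis=-1)


@dataclass
class PixelGrid:
    """A nested-ordered HEALPix sampling of the unit sphere."""

    n_side: int
    unit_vectors: np.ndarray  # (n_pix, 3)
    ordering: str = "nested"
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @property
    def n_pix(self) -> int:
        return self.unit_vectors.shape[0]

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.unit_vectors)
        return self._tree

    def coarsen(self) -> "PixelGrid":
        """The parent grid at half the resolution (4:1 pixel merge)."""
        if self.n_side == 1:
            raise ValueError("cannot coarsen below n_side=1")
        return healpix_sampling(self.n_side // 2)


def healpix_sampling(n_side: int) -> PixelGrid:
    """Build the nested HEALPix :class:`PixelGrid` at resolution ``n_side``."""
    n_side = _check_n_side(n_side)
    return PixelGrid(n_side=n_side, unit_vectors=pix2vec_nest(n_side))


def vec2pix_nest(grid: PixelGrid, vectors: np.ndarray) -> np.ndarray:
    """Nearest pixel-center index for each (unnormalized) direction vector.

    Nearest-neighbor lookup over pixel centers; used for resampling spherical
    maps under rotations.  Equivalent to exact HEALPix vec2pix up to ties on
    pixel boundaries (measure-zero set).
    """
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    v = v / np.where(norms == 0, 1.0, norms)
    _, idx = grid.tree.query(v)
    return idx
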