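"""Projection of property-attributed pocket surfaces onto spherical maps.

The normalized pocket mesh (centroid at the origin, max vertex norm 0.99) is
sampled by casting one ray per HEALPix pixel from the pixel's unit vector
toward the origin.  The first triangle hit yields nine per-pixel channels:

====== ===========================================================
index  channel
====== ===========================================================
0      depth: distance traveled from the unit sphere to the hit
1, 2   cos/sin of the angle between the outward face normal and the
       hit-to-pixel direction (two shape "normal maps")
3      electrostatic potential (mean of the 3 face vertices)
4      hydrophobicity (mean of the 3 face vertices)
5-8    DON, ACC, ALI, ARO pseudocenter bits (OR of the 3 vertices)
====== ===========================================================

Pixels whose ray misses the mesh (open pocket mouths) carry zeros in every
channel and are flagged in ``miss_mask``: they read as "far and featureless",
consistent with NULL vertices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .healpix import PixelGrid, vec2pix_nest
from .mesh import SurfaceMesh
from .properties import VertexProperties

__all__ = [
    "CHANNEL_NAMES", "SphericalMaps", "RaycastResult",
    "normalize_pocket", "raycast", "build_feature_maps",
    "random_rotation", "rotate_maps", "featurize",
]

CHANNEL_NAMES = ("depth", "cos_angle", "sin_angle", "charge",
                 "hydrophobicity", "DON", "ACC", "ALI", "ARO")


@dataclass
class SphericalMaps:
    """A 9 x n_pix signal on a nested HEALPix grid."""

    channels: np.ndarray   # (9, n_pix)
    miss_mask: np.ndarray  # (n_pix,) bool
    n_side: int

    def __post_init__(self):
        self.channels = np.asarray(self.channels, float)
        self.miss_mask = np.asarray(self.miss_mask, bool)
        if self.channels.shape != (9, 12 * self.n_side**2):
            raise ValueError(f"channels must be (9, {12 * self.n_side**2})")

    @property
    def n_pix(self) -> int:
        return self.channels.shape[1]


@dataclass
class RaycastResult:
    """Per-pixel first-intersection records for rays cast toward the origin."""

    hit: np.ndarray          # (n_pix,) bool
    distance: np.ndarray     # (n_pix,) ray parameter t (distance from sphere)
    face_id: np.ndarray      # (n_pix,) int, -1 on miss
    barycentric: np.ndarray  # (n_pix, 3)
    cos_theta: np.ndarray    # (n_pix,) normal-vs-return-direction cosine
    sin_theta: np.ndarray


def normalize_pocket(mesh: SurfaceMesh, target: float = 0.99) -> SurfaceMesh:
    """Center the vertex centroid at the origin and scale the mesh uniformly
    so the farthest vertex lies at radius ``target`` (< 1 keeps rays from
    starting exactly on the surface).  Idempotent."""
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    extent = np.linalg.norm(v, axis=1).max()
    if extent <= 0:
        raise ValueError("mesh has zero extent")
    return SurfaceMesh(v * (target / extent), mesh.faces.copy())


def raycast(mesh: SurfaceMesh, grid: PixelGrid, t_max: float = 1.0) -> RaycastResult:
    """First mesh intersection for rays from each pixel toward the origin.

    Each ray is the segment from the pixel's unit vector to the origin
    (``t_max = 1``); a pixel whose segment crosses no triangle — e.g. over the
    open mouth of a pocket — is flagged as a miss.  Vectorized Moller-Trumbore
    over ray/triangle candidate pairs: a triangle can only be hit when the ray
    direction falls inside the spherical cone spanned by the triangle's
    (projected) corners or its antipode; this exact culling keeps the
    candidate set small.  The hit angle is measured between the outward
    face normal and the direction from the hit point back to the pixel, so a
    sphere concentric with the origin gives cos(theta) = 1 for every pixel.
    """
    origins = grid.unit_vectors          # rays start on the unit sphere
    n_rays = len(origins)

    tri = mesh.vertices[mesh.faces]      # (m, 3, 3)
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    face_normals = mesh.face_normals

    # bounding cone of each triangle's direction footprint
    norms = np.linalg.norm(tri, axis=2)
    vdirs = tri / np.where(norms[..., None] == 0, 1.0, norms[..., None])
    axis = vdirs.mean(axis=1)
    axis_n = np.linalg.norm(axis, axis=1, keepdims=True)
    axis = axis / np.where(axis_n == 0, 1.0, axis_n)
    cos_half = np.einsum("mvk,mk->mv", vdirs, axis).min(axis=1) - 1e-9
    # a degenerate (origin-touching) cone must accept every ray
    cos_half = np.where(norms.min(axis=1) < 1e-12, -1.0, cos_half)

    cand = np.abs(origins @ axis.T) >= cos_half[None, :]   # (n_rays, m)
    ri, mi = np.nonzero(cand)

    t_best = np.full(n_rays, np.inf)
    face_id = np.full(n_rays, -1, dtype=np.int64)
    bary = np.zeros((n_rays, 3))
    eps = 1e-12

    for s0 in range(0, len(ri), 1 << 20):
        sl = slice(s0, s0 + (1 << 20))
        r, m = ri[sl], mi[sl]
        o = origins[r]
        d = -o
        pvec = np.cross(d, e2[m])
        det = np.einsum("pk,pk->p", e1[m], pvec)
        valid = np.abs(det) > eps
        inv_det = np.where(valid, 1.0 / np.where(valid, det, 1.0), 0.0)
        tvec = o - v0[m]
        u = np.einsum("pk,pk->p", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[m])
        v = np.einsum("pk,pk->p", d, qvec) * inv_det
        t = np.einsum("pk,pk->p", e2[m], qvec) * inv_det
        ok = (valid & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
              & (t > 1e-9) & (t <= t_max))
        if not ok.any():
            continue
        r, m, t, u, v = r[ok], m[ok], t[ok], u[ok], v[ok]
        # first hit per ray within this block
        order = np.lexsort((t, r))
        r_o = r[order]
        first = np.ones(len(r_o), dtype=bool)
        first[1:] = r_o[1:] != r_o[:-1]
        f = order[first]
        rf = r[f]
        better = t[f] < t_best[rf]
        f, rf = f[better], rf[better]
        t_best[rf] = t[f]
        face_id[rf] = m[f]
        bary[rf, 0] = 1.0 - u[f] - v[f]
        bary[rf, 1] = u[f]
        bary[rf, 2] = v[f]

    hit = face_id >= 0
    cos_t = np.zeros(n_rays)
    # direction from hit point back to the pixel is -d = +origin direction
    cos_t[hit] = np.einsum(
        "ik,ik->i", face_normals[face_id[hit]], origins[hit])
    cos_t = np.clip(cos_t, -1.0, 1.0)
    sin_t = np.where(hit, np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0)), 0.0)
    dist = np.where(hit, t_best, 0.0)
    return RaycastResult(hit=hit, distance=dist, face_id=face_id,
                         barycentric=bary, cos_theta=np.where(hit, cos_t, 0.0),
                         sin_theta=sin_t)


def build_feature_maps(hits: RaycastResult, mesh: SurfaceMesh,
                       props: VertexProperties, n_side: int) -> SphericalMaps:
    """Aggregate shape and vertex properties into the nine spherical maps.

    Continuous channels average the three face-vertex values; binary
    pseudocenter channels take the logical OR.  Missed pixels stay zero with
    ``miss_mask`` set.
    """
    n_pix = len(hits.hit)
    ch = np.zeros((9, n_pix))
    hit = hits.hit
    ch[0, hit] = np.clip(hits.distance[hit], 0.0, 1.0)
    ch[1, hit] = hits.cos_theta[hit]
    ch[2, hit] = hits.sin_theta[hit]
    fv = mesh.faces[hits.face_id[hit]]           # (h, 3) vertex ids
    ch[3, hit] = props.charge[fv].mean(axis=1)
    ch[4, hit] = props.hydrophobicity[fv].mean(axis=1)
    pseudo = props.pseudo[fv]                    # (h, 3, 4)
    ch[5:9, hit] = pseudo.max(axis=1).T
    return SphericalMaps(channels=ch, miss_mask=~hit, n_side=n_side)


def random_rotation(seed) -> np.ndarray:
    """A rotation matrix drawn uniformly from SO(3) (uniform unit quaternion),
    deterministic given the seed (an int or a Generator)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def rotate_maps(maps: SphericalMaps, rotation: np.ndarray,
                grid: PixelGrid) -> SphericalMaps:
    """Rotate a spherical signal by resampling: each output pixel takes the
    value of the input pixel nearest to the back-rotated direction.

    Equivalent (up to pixel-size discretization) to projecting the rotated
    pocket, and used as the training-time rotation augmentation on cached
    maps.
    """
    R = np.asarray(rotation, float)
    src = vec2pix_nest(grid, grid.unit_vectors @ R)  # R^-1 applied to centers
    return SphericalMaps(channels=maps.channels[:, src],
                         miss_mask=maps.miss_mask[src], n_side=maps.n_side)


def featurize(mesh: SurfaceMesh, props: VertexProperties,
              grid: PixelGrid) -> SphericalMaps:
    """Normalize, ray cast, and build the nine feature maps in one call."""
    norm = normalize_pocket(mesh)
    hits = raycast(norm, grid)
    return build_feature_maps(hits, norm, props, n_side=grid.n_side)
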