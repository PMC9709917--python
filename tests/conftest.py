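import warnings

import numpy as np
import pytest

from pocketsphere.healpix import healpix_sampling
from pocketsphere.maps import featurize, normalize_pocket
from pocketsphere.mesh import SurfaceMesh, smooth_mesh
from pocketsphere.pocket import (filter_spheres_by_hull, generate_pocket_spheres,
                                 select_binding_atoms, triangulate_surface)
from pocketsphere.properties import compute_vertex_properties
from pocketsphere.synth import ToyPocketSpec, make_toy_protein


@pytest.fixture(scope="session")
def grid16():
    return healpix_sampling(16)


@pytest.fixture(scope="session")
def grid2():
    return healpix_sampling(2)


@pytest.fixture(scope="session")
def toy_pipeline(grid16):
    """Full pocket pipeline on one deterministic toy protein: atoms, filtered
    spheres, smoothed mesh, vertex properties, normalized mesh, and maps."""
    atoms = make_toy_protein(ToyPocketSpec(cavity_radius=6.0, mouth_angle=60.0,
                                           seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spheres = generate_pocket_spheres(atoms)
        sel = select_binding_atoms(atoms, [atoms.ligand], r=6.0)
        filt = filter_spheres_by_hull(spheres, sel, atoms)
        mesh = smooth_mesh(triangulate_surface(filt), 4)
        props = compute_vertex_properties(mesh, atoms)
        norm = normalize_pocket(mesh)
        maps = featurize(mesh, props, grid16)
    return {"atoms": atoms, "spheres": spheres, "selected": sel,
            "filtered": filt, "mesh": mesh, "props": props,
            "normalized": norm, "maps": maps}


@pytest.fixture
def icosphere():
    """Unit icosphere factory as a SurfaceMesh (generic-position option)."""
    import trimesh

    def build(radius=0.5, subdivisions=2, offset=(0.0, 0.0, 0.0)):
        tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return SurfaceMesh(np.asarray(tm.vertices) + np.asarray(offset),
                           np.asarray(tm.faces))

    return build


def mt_raycast_oracle(mesh, grid, t_max=1.0):
    """Scalar per-ray/per-triangle Moller-Trumbore first-hit oracle."""
    ids, ts = [], []
    for o in grid.unit_vectors:
        d = -o
        best, bid = np.inf, -1
        for fi, f in enumerate(mesh.faces):
            a, b, c = mesh.vertices[f]
            e1, e2 = b - a, c - a
            p = np.cross(d, e2)
            det = e1 @ p
            if abs(det) < 1e-12:
                continue
            inv = 1.0 / det
            tv = o - a
            u = (tv @ p) * inv
            if u < -1e-9 or u > 1 + 1e-9:
                continue
            q = np.cross(tv, e1)
            v = (d @ q) * inv
            if v < -1e-9 or u + v > 1 + 1e-9:
                continue
            t = (e2 @ q) * inv
            if 1e-9 < t <= t_max and t < best:
                best, bid = t, fi
        ids.append(bid)
        ts.append(best if bid >= 0 else 0.0)
    return np.array(ids), np.array(ts)


def auc_pair_count_oracle(scores, labels):
    """O(n^2) Mann-Whitney AUC with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
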