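"""Physicochemical attribution of pocket-surface vertices.

Three vertex property groups are computed:

* **Pseudocenters** — points summarizing the interaction capability of
  pocket-lining functional groups: hydrogen-bond donor (DON), acceptor (ACC),
  mixed donor/acceptor (DAC), aliphatic (ALI), and aromatic/pi (ARO).  Each
  non-ALI center carries an interaction direction ``v``; its surface exposure
  direction ``r`` is the normalized sum of vectors to nearby mesh vertices.
  Centers whose ``v``/``r`` angle exceeds a per-kind cutoff (DON/ACC/ARO 100
  degrees, DAC 120) point away from the cavity and are discarded; ALI centers
  are isotropic and never filtered.  Each vertex is then one-hot encoded from
  its nearest surviving center within 3 A (DAC sets both DON and ACC bits); a
  vertex with no center in range is NULL (all-zero row).

* **Hydrophobicity** — atoms are binarized by partial-charge magnitude
  (nonpolar, |q| <= 0.25 e -> -1; polar, |q| > 0.25 e -> +1) and averaged over
  a 4.5 A sphere with inverse-distance weights (0.5 A floor), giving a value
  in [-1, 1] per vertex.

* **Electrostatic potential** — interpolated from an external scalar grid
  (OpenDX dialect) or computed by the built-in screened-Coulomb backend from
  per-atom charges, then capped to +/-30 kT/e and scaled to [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .atoms import AtomSet
from .mesh import SurfaceMesh

__all__ = [
    "Pseudocenter", "VertexProperties", "PSEUDO_KINDS", "DEFAULT_CUTOFFS",
    "build_pseudocenters", "exposure_vector", "filter_pseudocenters",
    "assign_pseudo_channels", "assign_hydrophobicity", "assign_electrostatics",
    "ScreenedCoulomb", "DXGrid", "read_dx", "compute_vertex_properties",
]

PSEUDO_KINDS = ("DON", "ACC", "DAC", "ALI", "ARO")
#: channel order of the binary vertex encoding
PSEUDO_CHANNELS = ("DON", "ACC", "ALI", "ARO")
#: v/r angle cutoffs in degrees; ALI is never filtered
DEFAULT_CUTOFFS = {"DON": 100.0, "ACC": 100.0, "DAC": 120.0, "ARO": 100.0}

# screened Coulomb in kT/e at 298 K: e^2/(4 pi eps0 * kT * 1 A)
_COULOMB_KT = 560.46


@dataclass
class Pseudocenter:
    kind: str                      # one of PSEUDO_KINDS
    position: np.ndarray           # (3,) Angstrom
    v: np.ndarray | None           # unit interaction direction; None for ALI
    source_residue: tuple          # (chain, resnum, resname)
    source_atoms: np.ndarray       # atom ids

    def __post_init__(self):
        if self.kind not in PSEUDO_KINDS:
            raise ValueError(f"unknown pseudocenter kind {self.kind!r}")
        self.position = np.asarray(self.position, float).reshape(3)
        if self.v is not None:
            self.v = np.asarray(self.v, float).reshape(3)
            n = np.linalg.norm(self.v)
            if n == 0:
                raise ValueError("zero-length interaction direction")
            self.v = self.v / n

    def transformed(self, rotation, translation=(0, 0, 0)) -> "Pseudocenter":
        R = np.asarray(rotation, float)
        return Pseudocenter(
            self.kind, self.position @ R.T + np.asarray(translation, float),
            None if self.v is None else self.v @ R.T,
            self.source_residue, self.source_atoms)


@dataclass
class VertexProperties:
    """Per-vertex property table aligned with a mesh's vertex order."""

    pseudo: np.ndarray          # (n, 4) binary over (DON, ACC, ALI, ARO)
    hydrophobicity: np.ndarray  # (n,) in [-1, 1]
    charge: np.ndarray          # (n,) in [-1, 1]

    def __post_init__(self):
        self.pseudo = np.asarray(self.pseudo)
        self.hydrophobicity = np.asarray(self.hydrophobicity, float)
        self.charge = np.asarray(self.charge, float)
        if self.pseudo.ndim != 2 or self.pseudo.shape[1] != 4:
            raise ValueError("pseudo must be (n, 4)")
        if not set(np.unique(self.pseudo)) <= {0, 1}:
            raise ValueError("pseudo entries must be binary")
        for name, arr, lim in (("hydrophobicity", self.hydrophobicity, 1.0),
                               ("charge", self.charge, 1.0)):
            if not np.all(np.isfinite(arr)) or np.any(np.abs(arr) > lim + 1e-12):
                raise ValueError(f"{name} out of range [-1, 1]")


def _load_templates(path=None):
    if path is None:
        src = resources.files("pocketsphere").joinpath("data/pseudocenter_templates.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("resname\t"):
            continue
        resname, kind, center_atoms, ref_atoms, v_rule = line.split("\t")
        rows.append((resname, kind, center_atoms.split(","),
                     [] if ref_atoms == "-" else ref_atoms.split(","), v_rule))
    return rows


def build_pseudocenters(atoms: AtomSet, template_path=None) -> list[Pseudocenter]:
    """Construct pseudocenters for every protein residue.

    Backbone rules are built in: the amide N yields a DON center with ``v``
    bisecting the C(prev)-N-CA angle, the carbonyl O an ACC center along C=O.
    Side-chain centers come from the residue template table.  Residues with
    missing template atoms skip that center with a warning; unknown residue
    names are skipped entirely.
    """
    templates = _load_templates(template_path)
    by_res: dict[tuple, dict[str, int]] = {}
    prot = atoms.protein
    order: list[tuple] = []
    for i in range(len(prot)):
        key = (prot.chain_ids[i], int(prot.res_ids[i]), prot.res_names[i])
        if key not in by_res:
            by_res[key] = {}
            order.append(key)
        by_res[key][prot.atom_names[i]] = i

    known_resnames = {t[0] for t in templates}
    centers: list[Pseudocenter] = []

    def pos(res, name):
        return prot.coords[res[name]]

    for key in order:
        chain, resid, resname = key
        res = by_res[key]
        has_backbone = {"N", "CA", "C", "O"} <= set(res)
        if resname not in known_resnames and not has_backbone:
            warnings.warn(f"unknown residue {resname} {chain}:{resid}, skipped",
                          stacklevel=2)
            continue

        if has_backbone:
            prev = (chain, resid - 1, None)
            prev_key = next((k for k in by_res
                             if k[0] == chain and k[1] == resid - 1 and "C" in by_res[k]),
                            None)
            if prev_key is not None:
                c_prev = prot.coords[by_res[prev_key]["C"]]
                n, ca = pos(res, "N"), pos(res, "CA")
                u1 = (n - c_prev) / np.linalg.norm(n - c_prev)
                u2 = (n - ca) / np.linalg.norm(n - ca)
                v = u1 + u2
                if np.linalg.norm(v) > 1e-12:
                    centers.append(Pseudocenter(
                        "DON", n, v, key, np.array([prot.ids[res["N"]]])))
            o, c = pos(res, "O"), pos(res, "C")
            centers.append(Pseudocenter(
                "ACC", o, o - c, key, np.array([prot.ids[res["O"]]])))

        for t_resname, kind, center_atoms, ref_atoms, v_rule in templates:
            if t_resname != resname:
                continue
            if not set(center_atoms) <= set(res) or not set(ref_atoms) <= set(res):
                missing = (set(center_atoms) | set(ref_atoms)) - set(res)
                warnings.warn(
                    f"{resname} {chain}:{resid} missing atoms {sorted(missing)}; "
                    f"{kind} center skipped", stacklevel=2)
                continue
            pts = np.array([pos(res, a) for a in center_atoms])
            p = pts.mean(axis=0)
            if v_rule == "away":
                ref = np.array([pos(res, a) for a in ref_atoms]).mean(axis=0)
                v = p - ref
            elif v_rule == "ring":
                # intrinsic sign: cross of the first ring edges in template order
                v = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            elif v_rule == "none":
                v = None
            else:
                raise ValueError(f"unknown v_rule {v_rule!r}")
            if v is not None and np.linalg.norm(v) < 1e-12:
                warnings.warn(f"degenerate direction for {kind} in {resname} "
                              f"{chain}:{resid}; center skipped", stacklevel=2)
                continue
            ids = prot.ids[[res[a] for a in center_atoms]]
            centers.append(Pseudocenter(kind, p, v, key, np.asarray(ids)))
    return centers


def exposure_vector(center: Pseudocenter, mesh: SurfaceMesh,
                    d_max: float = 3.0) -> np.ndarray | None:
    """Normalized sum of vectors from the center to mesh vertices within
    ``d_max``; ``None`` (undefined) when no vertex is in range or the sum
    cancels."""
    diff = mesh.vertices - center.position
    d = np.linalg.norm(diff, axis=1)
    near = diff[d <= d_max]
    if len(near) == 0:
        return None
    s = near.sum(axis=0)
    n = np.linalg.norm(s)
    if n < 1e-12:
        return None
    return s / n


def filter_pseudocenters(centers, mesh: SurfaceMesh,
                         cutoffs: dict | None = None,
                         d_max: float = 3.0) -> list[Pseudocenter]:
    """Keep centers whose interaction direction points toward the surface.

    A center is kept iff the angle between ``v`` and its exposure vector ``r``
    is at or below the per-kind cutoff (degrees).  ALI centers are always
    kept; non-ALI centers with undefined ``r`` are dropped (no exposure).
    """
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    kept = []
    for c in centers:
        if c.kind == "ALI":
            kept.append(c)
            continue
        r = exposure_vector(c, mesh, d_max=d_max)
        if r is None or c.v is None:
            continue
        angle = np.degrees(np.arccos(np.clip(np.dot(c.v, r), -1.0, 1.0)))
        if angle <= cutoffs[c.kind] + 1e-9:
            kept.append(c)
    return kept


def assign_pseudo_channels(mesh: SurfaceMesh, centers,
                           radius: float = 3.0) -> np.ndarray:
    """Binary (n, 4) vertex encoding over (DON, ACC, ALI, ARO).

    The single nearest center within ``radius`` sets the vertex channels (DAC
    sets both DON and ACC); vertices with no center in range stay all-zero
    (NULL).
    """
    out = np.zeros((mesh.n_vertices, 4), dtype=np.int8)
    if not centers:
        return out
    pos = np.array([c.position for c in centers])
    dist, idx = cKDTree(pos).query(mesh.vertices)
    hit = dist <= radius
    chan = {"DON": [0], "ACC": [1], "DAC": [0, 1], "ALI": [2], "ARO": [3]}
    for vi in np.flatnonzero(hit):
        out[vi, chan[centers[idx[vi]].kind]] = 1
    return out


def assign_hydrophobicity(mesh: SurfaceMesh, atoms: AtomSet,
                          radius: float = 4.5, charge_threshold: float = 0.25,
                          distance_floor: float = 0.5) -> np.ndarray:
    """Distance-weighted average of binarized atomic polarity.

    Atom value -1 for nonpolar (|q| <= threshold), +1 for polar; weights are
    inverse distance with a floor.  Vertices with no atom within ``radius``
    get 0.
    """
    prot = atoms.protein
    out = np.zeros(mesh.n_vertices)
    if len(prot) == 0:
        return out
    h = np.where(np.abs(prot.partial_charge) > charge_threshold, 1.0, -1.0)
    tree = cKDTree(prot.coords)
    neighbors = tree.query_ball_point(mesh.vertices, radius)
    for vi, idx in enumerate(neighbors):
        if not idx:
            continue
        d = np.linalg.norm(prot.coords[idx] - mesh.vertices[vi], axis=1)
        w = 1.0 / np.maximum(d, distance_floor)
        out[vi] = float(np.dot(w, h[idx]) / w.sum())
    return np.clip(out, -1.0, 1.0)


class ScreenedCoulomb:
    """Debye-screened Coulomb potential from per-atom point charges, in kT/e.

    phi(x) = C * sum_i q_i exp(-kappa d_i) / (eps_r d_i), with C the Coulomb
    constant expressed in kT/e per unit charge and Angstrom at 298 K.
    """

    def __init__(self, atoms: AtomSet, kappa: float = 0.1, eps_r: float = 4.0):
        prot = atoms.protein
        self.coords = prot.coords
        self.charges = prot.partial_charge
        self.kappa = float(kappa)
        self.eps_r = float(eps_r)

    def potential(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, float).reshape(-1, 3)
        out = np.zeros(len(points))
        if len(self.coords) == 0:
            return out
        for s0 in range(0, len(points), 1024):
            sl = slice(s0, s0 + 1024)
            d = np.linalg.norm(points[sl, None, :] - self.coords[None, :, :], axis=2)
            d = np.maximum(d, 0.1)
            out[sl] = (_COULOMB_KT / self.eps_r) * (
                self.charges * np.exp(-self.kappa * d) / d).sum(axis=1)
        return out


@dataclass
class DXGrid:
    """Axis-aligned scalar grid in the OpenDX dialect written by
    Poisson-Boltzmann solvers."""

    origin: np.ndarray   # (3,)
    delta: np.ndarray    # (3,) spacing along each axis
    values: np.ndarray   # (nx, ny, nz)

    def potential(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, float).reshape(-1, 3)
        axes = [self.origin[k] + self.delta[k] * np.arange(self.values.shape[k])
                for k in range(3)]
        lo = np.array([ax[0] for ax in axes])
        hi = np.array([ax[-1] for ax in axes])
        pmin, pmax = points.min(axis=0), points.max(axis=0)
        if np.any(pmin < lo - 1e-9) or np.any(pmax > hi + 1e-9):
            raise ValueError(
                "potential grid does not cover the mesh bounding box: grid "
                f"[{lo}, {hi}] vs mesh [{pmin}, {pmax}]")
        interp = RegularGridInterpolator(axes, self.values)
        return interp(points)


def read_dx(path) -> DXGrid:
    """Parse an OpenDX scalar field (gridpositions/gridconnections dialect)."""
    counts = origin = None
    deltas = []
    data: list[float] = []
    n_expected = None
    for line in Path(path).read_text().splitlines():
        t = line.split()
        if not t or t[0] == "#":
            continue
        if t[0] == "object" and "gridpositions" in line:
            counts = np.array(t[-3:], dtype=int)
        elif t[0] == "origin":
            origin = np.array(t[1:4], dtype=float)
        elif t[0] == "delta":
            deltas.append(np.array(t[1:4], dtype=float))
        elif t[0] == "object" and "array" in line:
            n_expected = int(t[t.index("items") + 1])
        elif t[0] in ("attribute", "component", "object", "end"):
            continue
        else:
            data.extend(float(x) for x in t)
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"malformed DX header in {path}")
    values = np.array(data[: int(np.prod(counts))])
    if n_expected is not None and len(values) < n_expected:
        raise ValueError(f"DX data truncated: {len(values)} < {n_expected}")
    delta = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    return DXGrid(origin, delta, values.reshape(counts))


def assign_electrostatics(mesh: SurfaceMesh, potential_source,
                          cap: float = 30.0) -> np.ndarray:
    """Vertex potential capped to +/-``cap`` and scaled to [-1, 1]."""
    phi = np.asarray(potential_source.potential(mesh.vertices), float)
    return np.clip(phi, -cap, cap) / cap


def compute_vertex_properties(mesh: SurfaceMesh, atoms: AtomSet,
                              potential_source=None,
                              cutoffs: dict | None = None,
                              pseudo_radius: float = 3.0,
                              exposure_d_max: float = 3.0,
                              hydrophobicity_radius: float = 4.5,
                              template_path=None) -> VertexProperties:
    """Run the full property stage: pseudocenters (built, exposure-filtered,
    projected), hydrophobicity, and electrostatics (screened Coulomb unless a
    grid is given)."""
    centers = build_pseudocenters(atoms, template_path=template_path)
    centers = filter_pseudocenters(centers, mesh, cutoffs=cutoffs,
                                   d_max=exposure_d_max)
    pseudo = assign_pseudo_channels(mesh, centers, radius=pseudo_radius)
    hydro = assign_hydrophobicity(mesh, atoms, radius=hydrophobicity_radius)
    source = potential_source or ScreenedCoulomb(atoms)
    charge = assign_electrostatics(mesh, source)
    return VertexProperties(pseudo=pseudo, hydrophobicity=hydro, charge=charge)
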