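"""Synthetic fixtures: toy pocket proteins and labeled spherical-map datasets.

``make_toy_protein`` builds a desk-scale pseudo-protein whose atoms line a
spherical-cap cavity: functional groups (donor / acceptor / aromatic /
aliphatic / charged) sit on a shell of the requested cavity radius with their
interaction directions pointing at the cavity center, a dummy ligand floats
inside, and an opening of the requested mouth angle is left around +z.  Five
minimal pseudo-residue types (TDN, TAC, TAR, TAL, TCP/TCN) exercise the
pseudocenter template machinery without a rotamer library.

``make_map_dataset`` skips the geometry stage and directly generates labeled
9-channel spherical maps: each class is a fixed combination of smooth
spherical-cap motifs on chosen channels, each sample is a randomly rotated,
noisy rendering of its class motif, so class identity is orientation-free by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atoms import AtomSet, from_arrays
from .healpix import healpix_sampling
from .maps import CHANNEL_NAMES, SphericalMaps, random_rotation

__all__ = ["ToyPocketSpec", "make_toy_protein", "make_map_dataset",
           "make_pair_dataset", "SmoothPocketMaps", "make_smooth_pocket"]

LINING_KINDS = ("donor", "acceptor", "aromatic", "aliphatic", "charged")


@dataclass
class ToyPocketSpec:
    cavity_radius: float = 6.0          # Angstrom, shell radius of lining atoms
    mouth_angle: float = 60.0           # degrees, full opening angle about +z
    lining: tuple = (("donor", 0.25), ("acceptor", 0.25),
                     ("aromatic", 0.25), ("aliphatic", 0.25))
    noise_sd: float = 0.0               # Angstrom, positional jitter
    seed: int = 0
    site_spacing: float = 2.6           # Angstrom between lining sites

    def __post_init__(self):
        if not 3.0 <= self.cavity_radius <= 12.0:
            raise ValueError("cavity_radius must be within [3, 12] A")
        total = sum(f for _, f in self.lining)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"lining fractions must sum to 1, got {total}")
        if any(k not in LINING_KINDS or f < 0 for k, f in self.lining):
            raise ValueError(f"lining kinds must be in {LINING_KINDS} with "
                             "nonnegative fractions")


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic, roughly uniform unit directions."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1 + 5**0.5) * i
    st = np.sqrt(1 - z**2)
    return np.stack([st * np.cos(phi), st * np.sin(phi), z], axis=1)


def _orthonormal_tangents(u: np.ndarray):
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(u, a)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(u, t1)


def _residue_atoms(kind: str, u: np.ndarray, radius: float, alt: bool):
    """(resname, [(atom_name, element, offset_coord, charge)]) for one site.

    ``u`` is the outward shell direction; the functional atom sits at
    ``radius * u`` with its interaction direction facing the cavity center.
    """
    t1, t2 = _orthonormal_tangents(u)
    inner = radius * u
    if kind == "donor":
        return "TDN", [("N1", "N", inner, 0.40), ("C1", "C", inner + 1.4 * u, 0.0)]
    if kind == "acceptor":
        return "TAC", [("O1", "O", inner, -0.40), ("C1", "C", inner + 1.3 * u, 0.0)]
    if kind == "aliphatic":
        return "TAL", [("C1", "C", inner, 0.05), ("C2", "C", inner + 1.5 * u, 0.05)]
    if kind == "charged":
        if alt:
            return "TCN", [("O1", "O", inner, -0.60), ("C1", "C", inner + 1.3 * u, 0.0)]
        return "TCP", [("N1", "N", inner, 0.60), ("C1", "C", inner + 1.4 * u, 0.0)]
    if kind == "aromatic":
        centroid = (radius + 0.2) * u
        atoms = []
        # clockwise order about u so the template ring normal faces the cavity
        for j, ang in enumerate(-np.arange(6) * np.pi / 3):
            p = centroid + 1.39 * (np.cos(ang) * t1 + np.sin(ang) * t2)
            atoms.append((f"C{j + 1}", "C", p, 0.0))
        return "TAR", atoms
    raise ValueError(f"unknown lining kind {kind!r}")


def _allocate_counts(fractions, n: int) -> list[int]:
    """Largest-remainder apportionment of n sites to the lining fractions."""
    raw = [f * n for _, f in fractions]
    counts = [int(r) for r in raw]
    rest = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:rest]:
        counts[i] += 1
    return counts


def make_toy_protein(spec: ToyPocketSpec) -> AtomSet:
    """Deterministic toy protein with a concave, ligand-occupied pocket."""
    rng = np.random.default_rng(spec.seed)
    n_sites = max(8, int(4 * np.pi * spec.cavity_radius**2 / spec.site_spacing**2))
    dirs = _fibonacci_directions(n_sites)
    # leave the mouth open around +z
    half = np.radians(spec.mouth_angle) / 2.0
    keep = np.arccos(np.clip(dirs[:, 2], -1, 1)) >= half
    dirs = dirs[keep]
    if len(dirs) < 4:
        raise ValueError("mouth angle leaves too few lining sites")

    counts = _allocate_counts(spec.lining, len(dirs))
    kinds = [k for (k, _), c in zip(spec.lining, counts) for _ in range(c)]

    names, elements, coords, charges, resnames, resids = [], [], [], [], [], []
    charged_alt = False
    for i, (u, kind) in enumerate(zip(dirs, kinds)):
        resname, atoms = _residue_atoms(kind, u, spec.cavity_radius, charged_alt)
        if kind == "charged":
            charged_alt = not charged_alt
        for name, el, p, q in atoms:
            names.append(name)
            elements.append(el)
            coords.append(p)
            charges.append(q)
            resnames.append(resname)
            resids.append(i + 1)
    coords = np.array(coords)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)

    protein = AtomSet(
        ids=np.arange(len(coords)),
        coords=coords,
        elements=np.array(elements),
        chain_ids=np.full(len(coords), "A"),
        res_ids=np.array(resids),
        res_names=np.array(resnames),
        atom_names=np.array(names),
        vdw_radius=np.array([{"N": 1.55, "O": 1.52, "C": 1.70}[e] for e in elements]),
        partial_charge=np.array(charges),
        is_ligand=np.zeros(len(coords), bool),
        is_heavy=np.ones(len(coords), bool),
    )

    # dummy tetrahedral ligand at the cavity center, sized so the lining
    # shell stays within ligand-selection reach for any cavity radius
    lig_size = max(0.8, spec.cavity_radius - 4.5)
    lig_coords = lig_size * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / 3**0.5
    ligand = from_arrays(lig_coords, "C", res_names="LIG", res_ids=resids[-1] + 1,
                         atom_names=[f"C{i+1}" for i in range(4)], is_ligand=True)
    ligand.ids = ligand.ids + len(protein)

    return AtomSet(**{k: np.concatenate([getattr(protein, k), getattr(ligand, k)])
                      for k in ("ids", "coords", "elements", "chain_ids", "res_ids",
                                "res_names", "atom_names", "vdw_radius",
                                "partial_charge", "is_ligand", "is_heavy")})


# channels a class motif may use to distinguish itself
_DEFAULT_MOTIF_CHANNELS = ("depth", "charge", "hydrophobicity", "DON", "ACC")
_BINARY = {"DON", "ACC", "ALI", "ARO"}


def _class_motif(class_id: int, seed: int, channels, caps_per_channel: int = 2):
    """Fixed per-class cap motifs: (channel index, direction, width, amplitude)."""
    rng = np.random.default_rng([seed, class_id])
    motifs = []
    for ch in channels:
        ci = CHANNEL_NAMES.index(ch)
        for _ in range(caps_per_channel):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            width = rng.uniform(0.35, 0.6)          # radians
            amp = rng.uniform(0.5, 0.9) * rng.choice([-1.0, 1.0])
            if ch in _BINARY or ch == "depth":
                amp = abs(amp)
            motifs.append((ci, d, width, amp))
    return motifs


def make_map_dataset(n_classes: int, n_per_class: int, n_side: int = 16,
                     seed: int = 0, noise_sd: float = 0.02,
                     motif_channels=_DEFAULT_MOTIF_CHANNELS):
    """Labeled synthetic spherical maps with orientation-free class structure.

    Each class is a fixed set of smooth spherical-cap motifs on
    ``motif_channels``; every sample renders its class motif under an
    independent uniform rotation plus Gaussian noise on the continuous
    channels.  Restricting ``motif_channels`` (e.g. to ``("charge",)``)
    produces classes indistinguishable on all other channels, for feature
    ablation checks.  Returns (list of SphericalMaps, labels array).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    grid = healpix_sampling(n_side)
    pix = grid.unit_vectors
    rng = np.random.default_rng(seed)
    motifs = {c: _class_motif(c, seed, motif_channels) for c in range(n_classes)}

    maps_list, labels = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            R = random_rotation(rng)
            ch = np.zeros((9, grid.n_pix))
            ch[0] = 0.5          # smooth featureless pocket baseline
            ch[1] = 1.0
            for ci, d, width, amp in motifs[c]:
                ang = np.arccos(np.clip(pix @ (R @ d), -1, 1))
                if CHANNEL_NAMES[ci] in _BINARY:
                    ch[ci] = np.maximum(ch[ci], (ang <= width).astype(float))
                else:
                    ch[ci] += amp * np.exp(-((ang / width) ** 2))
            # continuous noise, then enforce per-channel ranges
            for ci in (0, 3, 4):
                ch[ci] += rng.normal(0.0, noise_sd, grid.n_pix)
            ch[0] = np.clip(ch[0], 0.0, 1.0)
            ch[1] = np.clip(ch[1] + rng.normal(0.0, noise_sd, grid.n_pix), -1.0, 1.0)
            ch[2] = np.sqrt(np.clip(1.0 - ch[1] ** 2, 0.0, 1.0))
            ch[3] = np.clip(ch[3], -1.0, 1.0)
            ch[4] = np.clip(ch[4], -1.0, 1.0)
            maps_list.append(SphericalMaps(ch, np.zeros(grid.n_pix, bool), n_side))
            labels.append(c)
    return maps_list, np.array(labels)


class SmoothPocketMaps:
    """A band-limited synthetic pocket defined directly in map space.

    Continuous channels (depth, charge, hydrophobicity) carry Gaussian
    spherical-cap motifs; shape normal channels are consistent smooth fields;
    binary channels stay zero.  Because the signal is analytic in the
    direction, the pocket can be rendered under any rotation *exactly* (no
    resampling), which makes it the reference input for quantifying the
    rotation equivariance of the network: discontinuous (binary) channels
    alias at pixel boundaries no matter the architecture.
    """

    def __init__(self, seed: int, n_side: int = 16, n_caps: int = 2):
        self.n_side = n_side
        self.grid = healpix_sampling(n_side)
        rng = np.random.default_rng(seed)
        self.motifs = []
        for ci in (0, 3, 4):   # depth, charge, hydrophobicity
            for _ in range(n_caps):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                self.motifs.append((ci, d, rng.uniform(0.35, 0.6),
                                    rng.uniform(0.4, 0.8) * rng.choice([-1, 1])))

    def render(self, rotation: np.ndarray | None = None) -> SphericalMaps:
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        pix = self.grid.unit_vectors
        ch = np.zeros((9, self.grid.n_pix))
        ch[0] = 0.5
        ch[1] = 1.0
        for ci, d, width, amp in self.motifs:
            ang = np.arccos(np.clip(pix @ (R @ d), -1, 1))
            ch[ci] += amp * np.exp(-((ang / width) ** 2))
        ch[0] = np.clip(ch[0], 0.0, 1.0)
        ch[1] = np.clip(ch[1], -1.0, 1.0)
        ch[2] = np.sqrt(np.clip(1.0 - ch[1] ** 2, 0.0, 1.0))
        ch[3] = np.clip(ch[3], -1.0, 1.0)
        ch[4] = np.clip(ch[4], -1.0, 1.0)
        return SphericalMaps(ch, np.zeros(self.grid.n_pix, bool), self.n_side)


def make_smooth_pocket(seed: int, n_side: int = 16) -> SmoothPocketMaps:
    """Convenience constructor for a :class:`SmoothPocketMaps` instance."""
    return SmoothPocketMaps(seed, n_side=n_side)


def make_pair_dataset(maps, labels, n_pos: int, n_neg: int, seed: int = 0):
    """Within-class positive and cross-class negative pairs, no duplicates.

    Returns a list of (id_a, id_b, label) tuples, deterministic per seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
    if len(idx_by_class) < 2:
        raise ValueError("need at least 2 classes for pairs")

    pos_all = [(int(i), int(j)) for c, idx in idx_by_class.items()
               for a, i in enumerate(idx) for j in idx[a + 1:]]
    neg_all = [(int(i), int(j)) for ci, ii in idx_by_class.items()
               for cj, jj in idx_by_class.items() if ci < cj
               for i in ii for j in jj]
    if n_pos > len(pos_all) or n_neg > len(neg_all):
        raise ValueError(
            f"requested {n_pos}+{n_neg} pairs but only {len(pos_all)} positive "
            f"and {len(neg_all)} negative combinations exist")
    pos = [pos_all[i] for i in rng.choice(len(pos_all), n_pos, replace=False)]
    neg = [neg_all[i] for i in rng.choice(len(neg_all), n_neg, replace=False)]
    return [(a, b, 1) for a, b in pos] + [(a, b, 0) for a, b in neg]
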