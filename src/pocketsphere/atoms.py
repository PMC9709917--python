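"""Atom containers and structure file I/O.

An :class:`AtomSet` is a column-oriented view of a (sub)structure: coordinates,
element, residue identity, van der Waals radius, partial charge, and
ligand/heavy flags.  PDB files are parsed with biotite; PQR files (the
whitespace dialect written by charge-assignment tools, which adds per-atom
charge and radius columns) are parsed by a small reader since no installed
library covers that dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = ["AtomSet", "read_pdb", "read_pqr", "write_pdb", "VDW_RADII"]

# Bondi van der Waals radii (Angstrom) for the supported element subset.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.00, "MN": 2.00,
    "NA": 2.27, "K": 2.75, "CU": 1.40, "NI": 1.63, "CO": 2.00,
}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "SOL"}


@dataclass
class AtomSet:
    """Parsed structure: one row per atom.

    Invariants: finite coordinates, positive vdW radii, known elements,
    ligand and protein atoms disjoint (a single boolean per atom).
    """

    ids: np.ndarray            # (n,) int
    coords: np.ndarray         # (n, 3) float, Angstrom
    elements: np.ndarray       # (n,) str
    chain_ids: np.ndarray      # (n,) str
    res_ids: np.ndarray        # (n,) int
    res_names: np.ndarray      # (n,) str
    atom_names: np.ndarray     # (n,) str
    vdw_radius: np.ndarray     # (n,) float, Angstrom
    partial_charge: np.ndarray  # (n,) float, e
    is_ligand: np.ndarray      # (n,) bool
    is_heavy: np.ndarray       # (n,) bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for name in ("ids", "elements", "chain_ids", "res_ids", "res_names",
                     "atom_names", "vdw_radius", "partial_charge",
                     "is_ligand", "is_heavy"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"field {name!r} length {arr.shape[0]} != {n} atoms")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.vdw_radius <= 0):
            raise ValueError("vdw_radius must be positive")
        unknown = set(np.char.upper(self.elements.astype(str))) - set(VDW_RADII)
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, mask: np.ndarray) -> "AtomSet":
        mask = np.asarray(mask)
        return AtomSet(**{k: getattr(self, k)[mask] for k in (
            "ids", "coords", "elements", "chain_ids", "res_ids", "res_names",
            "atom_names", "vdw_radius", "partial_charge", "is_ligand", "is_heavy")})

    @property
    def protein(self) -> "AtomSet":
        return self.subset(~self.is_ligand)

    @property
    def ligand(self) -> "AtomSet":
        return self.subset(self.is_ligand)

    @property
    def ligand_heavy(self) -> "AtomSet":
        return self.subset(self.is_ligand & self.is_heavy)

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "AtomSet":
        """Rigidly transformed copy (x -> R x + t)."""
        out = self.subset(np.ones(len(self), dtype=bool))
        out.coords = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return out


def _vdw_of(elements: np.ndarray) -> np.ndarray:
    return np.array([VDW_RADII[e.upper()] for e in elements])


def from_arrays(coords, elements, res_names="UNK", res_ids=1, chain_ids="A",
                atom_names=None, partial_charge=0.0, is_ligand=False) -> AtomSet:
    """Convenience constructor broadcasting scalar metadata over n atoms."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    elements = np.broadcast_to(np.asarray(elements, dtype=object), (n,)).astype(str)
    if atom_names is None:
        atom_names = elements
    return AtomSet(
        ids=np.arange(n),
        coords=coords,
        elements=elements,
        chain_ids=np.broadcast_to(np.asarray(chain_ids, dtype=object), (n,)).astype(str),
        res_ids=np.broadcast_to(np.asarray(res_ids), (n,)).astype(int),
        res_names=np.broadcast_to(np.asarray(res_names, dtype=object), (n,)).astype(str),
        atom_names=np.broadcast_to(np.asarray(atom_names, dtype=object), (n,)).astype(str),
        vdw_radius=_vdw_of(elements),
        partial_charge=np.broadcast_to(np.asarray(partial_charge, dtype=float), (n,)).copy(),
        is_ligand=np.broadcast_to(np.asarray(is_ligand, dtype=bool), (n,)).copy(),
        is_heavy=np.char.upper(elements) != "H",
    )


def _from_atom_array(arr: struc.AtomArray, hetero_ligand: np.ndarray,
                     charges: np.ndarray | None = None,
                     radii: np.ndarray | None = None) -> AtomSet:
    elements = arr.element.astype(str)
    return AtomSet(
        ids=np.arange(arr.array_length()),
        coords=np.asarray(arr.coord, dtype=float),
        elements=elements,
        chain_ids=arr.chain_id.astype(str),
        res_ids=np.asarray(arr.res_id, dtype=int),
        res_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        vdw_radius=_vdw_of(elements) if radii is None else np.asarray(radii, float),
        partial_charge=np.zeros(arr.array_length()) if charges is None
        else np.asarray(charges, float),
        is_ligand=hetero_ligand,
        is_heavy=np.char.upper(elements) != "H",
    )


def read_pdb(path, ligand_resname: str | None = None,
             ligand_chain: str | None = None) -> AtomSet:
    """Read the first model of a PDB file.

    The ligand is taken to be all non-water HETATM records by default, or
    restricted to a residue name (and optionally a chain).
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    ligand = arr.hetero & ~np.isin(arr.res_name, list(_WATER_NAMES))
    if ligand_resname is not None:
        ligand &= arr.res_name == ligand_resname
    if ligand_chain is not None:
        ligand &= arr.chain_id == ligand_chain
    return _from_atom_array(arr, ligand)


def read_pqr(path, ligand_resname: str | None = None) -> AtomSet:
    """Read a whitespace-delimited PQR file (charge and radius columns)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        t = line.split()
        # ATOM id name resname [chain] resid x y z q r
        if len(t) == 11:
            _, aid, name, resn, chain, resi, x, y, z, q, r = t
        elif len(t) == 10:
            _, aid, name, resn, resi, x, y, z, q, r = t
            chain = "A"
        else:
            raise ValueError(f"unparseable PQR line: {line!r}")
        rows.append((line.startswith("HETATM"), name, resn, chain, int(resi),
                     float(x), float(y), float(z), float(q), float(r)))
    if not rows:
        raise ValueError(f"no atoms in PQR file {path}")
    het = np.array([r[0] for r in rows])
    names = np.array([r[1] for r in rows])
    resn = np.array([r[2] for r in rows])
    elements = np.array([_element_from_name(n) for n in names])
    ligand = het & ~np.isin(resn, list(_WATER_NAMES))
    if ligand_resname is not None:
        ligand &= resn == ligand_resname
    return AtomSet(
        ids=np.arange(len(rows)),
        coords=np.array([r[5:8] for r in rows], dtype=float),
        elements=elements,
        chain_ids=np.array([r[3] for r in rows]),
        res_ids=np.array([r[4] for r in rows]),
        res_names=resn,
        atom_names=names,
        vdw_radius=np.array([r[9] for r in rows], dtype=float),
        partial_charge=np.array([r[8] for r in rows], dtype=float),
        is_ligand=ligand,
        is_heavy=np.char.upper(elements) != "H",
    )


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB/PQR atom name."""
    stripped = name.strip().lstrip("0123456789")
    two = stripped[:2].upper()
    if two in VDW_RADII and two not in {"CA", "CO", "NI"}:  # ambiguous with C-alpha etc.
        # only accept 2-letter symbols when the first letter alone is not an element
        if stripped[0].upper() not in VDW_RADII:
            return two
    one = stripped[0].upper()
    if one in VDW_RADII:
        return one
    raise ValueError(f"cannot infer element from atom name {name!r}")


def write_pdb(atoms: AtomSet, path) -> None:
    """Write an AtomSet to PDB (ligand atoms as HETATM)."""
    arr = struc.AtomArray(len(atoms))
    arr.coord = atoms.coords.astype(np.float32)
    arr.chain_id = atoms.chain_ids
    arr.res_id = atoms.res_ids
    arr.res_name = atoms.res_names
    arr.atom_name = atoms.atom_names
    arr.element = np.char.upper(atoms.elements.astype(str))
    arr.hetero = atoms.is_ligand
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
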