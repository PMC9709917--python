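"""Attribute a pocket surface with physicochemical properties.

Continues from the pocket-surface example: places pseudocenters on the
pocket-lining residues, filters them by surface exposure (the angle between
each center's interaction direction v and its exposure vector r), and writes
per-vertex donor/acceptor/aliphatic/aromatic bits, hydrophobicity, and
screened-Coulomb electrostatic potential.
"""

import warnings
from collections import Counter

from pocketsphere import (ToyPocketSpec, build_pseudocenters,
                          compute_vertex_properties, filter_pseudocenters,
                          filter_spheres_by_hull, generate_pocket_spheres,
                          make_toy_protein, select_binding_atoms, smooth_mesh,
                          triangulate_surface)

warnings.simplefilter("ignore")

atoms = make_toy_protein(ToyPocketSpec(cavity_radius=6.0, mouth_angle=60.0,
                                       seed=1))
spheres = generate_pocket_spheres(atoms)
selected = select_binding_atoms(atoms, [atoms.ligand], r=6.0)
mesh = smooth_mesh(triangulate_surface(
    filter_spheres_by_hull(spheres, selected, atoms)), 4)

centers = build_pseudocenters(atoms)
kept = filter_pseudocenters(centers, mesh)
print("pseudocenters by kind (built -> exposure-filtered):")
built = Counter(c.kind for c in centers)
after = Counter(c.kind for c in kept)
for kind in ("DON", "ACC", "DAC", "ALI", "ARO"):
    print(f"  {kind}: {built.get(kind, 0)} -> {after.get(kind, 0)}")

props = compute_vertex_properties(mesh, atoms)
frac_null = (props.pseudo.sum(axis=1) == 0).mean()
print(f"vertices: {len(props.hydrophobicity)}; NULL (no center within 3 A): "
      f"{100 * frac_null:.1f}%")
print(f"hydrophobicity range [{props.hydrophobicity.min():.2f}, "
      f"{props.hydrophobicity.max():.2f}] (-1 nonpolar, +1 polar environment)")
print(f"normalized potential range [{props.charge.min():.2f}, "
      f"{props.charge.max():.2f}] (+/-1 is the +/-30 kT/e cap)")
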