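"""Pseudocenters, exposure filtering, hydrophobicity, electrostatics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from pocketsphere.atoms import AtomSet, from_arrays
from pocketsphere.mesh import SurfaceMesh
from pocketsphere.properties import (DXGrid, Pseudocenter, ScreenedCoulomb,
                                     assign_electrostatics,
                                     assign_hydrophobicity,
                                     assign_pseudo_channels,
                                     build_pseudocenters, exposure_vector,
                                     filter_pseudocenters, read_dx)


def residue(res_name, names, coords, res_id=1):
    elements = [n[0] for n in names]
    return AtomSet(
        ids=np.arange(len(names)), coords=np.asarray(coords, float),
        elements=np.array(elements), chain_ids=np.full(len(names), "A"),
        res_ids=np.full(len(names), res_id), res_names=np.full(len(names), res_name),
        atom_names=np.array(names),
        vdw_radius=np.full(len(names), 1.6),
        partial_charge=np.zeros(len(names)),
        is_ligand=np.zeros(len(names), bool), is_heavy=np.ones(len(names), bool))


def cat(*sets):
    fields = ("ids", "coords", "elements", "chain_ids", "res_ids", "res_names",
              "atom_names", "vdw_radius", "partial_charge", "is_ligand", "is_heavy")
    merged = {k: np.concatenate([getattr(s, k) for s in sets]) for k in fields}
    merged["ids"] = np.arange(len(merged["ids"]))
    return AtomSet(**merged)


class TestBuildPseudocenters:
    def test_backbone_amide_bisector(self):
        """In a glycine dipeptide the second residue's amide N yields a donor
        whose direction bisects the C(prev)-N-CA angle."""
        res1 = residue("GLY", ["N", "CA", "C", "O"],
                       [[0, 0, 0], [1.5, 0, 0], [2.2, 1.2, 0], [1.7, 2.3, 0]],
                       res_id=1)
        res2 = residue("GLY", ["N", "CA", "C", "O"],
                       [[3.5, 1.2, 0], [4.4, 2.3, 0], [5.9, 2.0, 0], [6.5, 0.9, 0]],
                       res_id=2)
        atoms = cat(res1, res2)
        centers = build_pseudocenters(atoms)
        n2 = [c for c in centers if c.kind == "DON"
              and c.source_residue[1] == 2][0]
        n = atoms.coords[4]
        u1 = (n - atoms.coords[2]) / np.linalg.norm(n - atoms.coords[2])  # N - C(prev)
        u2 = (n - atoms.coords[5]) / np.linalg.norm(n - atoms.coords[5])  # N - CA
        expected = (u1 + u2) / np.linalg.norm(u1 + u2)
        np.testing.assert_allclose(n2.v, expected, atol=1e-12)
        np.testing.assert_allclose(n2.position, n)

    def test_backbone_carbonyl_acceptor(self):
        res = residue("GLY", ["N", "CA", "C", "O"],
                      [[0, 0, 0], [1.5, 0, 0], [2.2, 1.2, 0], [1.7, 2.3, 0]])
        acc = [c for c in build_pseudocenters(res) if c.kind == "ACC"][0]
        expected = res.coords[3] - res.coords[2]
        np.testing.assert_allclose(acc.v, expected / np.linalg.norm(expected))

    def test_phenylalanine_ring_normal(self):
        """Plane-fit oracle: the ARO direction is orthogonal to every ring
        edge of an ideal phenyl ring."""
        ring = [(np.cos(a), np.sin(a), 0.0) for a in np.pi / 3 * np.arange(6)]
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        order = [0, 1, 5, 2, 4, 3]  # template order around the ring
        coords = [ring[i] for i in order]
        res = residue("PHE", names + ["CB"], coords + [[2.0, 0, 0.5]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aro = [c for c in build_pseudocenters(res) if c.kind == "ARO"][0]
        pts = np.array([ring[i] for i in order])
        for i in range(6):
            edge = pts[i] - pts[(i + 1) % 6]
            assert abs(np.dot(aro.v, edge)) < 1e-9
        np.testing.assert_allclose(aro.position, np.zeros(3), atol=1e-12)

    def test_histidine_ring_nitrogens_are_dac(self):
        coords = {"CG": [0, 0, 0], "ND1": [1.3, 0.7, 0], "CD2": [0.3, -1.3, 0],
                  "CE1": [2.3, -0.2, 0], "NE2": [1.6, -1.4, 0]}
        res = residue("HIS", list(coords), list(coords.values()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kinds = [(c.kind, c.source_atoms) for c in build_pseudocenters(res)]
        dacs = [k for k, _ in kinds if k == "DAC"]
        assert len(dacs) == 2

    def test_missing_atoms_skip_with_warning(self):
        res = residue("LYS", ["CB", "CG"], [[0, 0, 0], [1.5, 0, 0]])
        with pytest.warns(UserWarning, match="missing"):
            centers = build_pseudocenters(res)
        assert all(c.kind != "DON" for c in centers)

    def test_unknown_residue_skipped(self):
        res = residue("XXX", ["C1"], [[0, 0, 0]])
        with pytest.warns(UserWarning, match="unknown"):
            assert build_pseudocenters(res) == []


def _center(kind, position, v):
    return Pseudocenter(kind, position, v, ("A", 1, "TST"), np.array([0]))


class TestExposureVector:
    def _mesh_of_points(self, pts):
        """Mesh whose vertex set is the given points (faces unused here)."""
        pts = np.asarray(pts, float)
        faces = np.array([[0, min(1, len(pts) - 1), min(2, len(pts) - 1)]])
        return SurfaceMesh(pts, faces)

    def test_single_vertex_direction(self):
        mesh = self._mesh_of_points([[2.9, 0, 0]])
        r = exposure_vector(_center("DON", [0, 0, 0], [1, 0, 0]), mesh, 3.0)
        np.testing.assert_allclose(r, [1, 0, 0])

    def test_symmetric_cancellation_undefined(self):
        mesh = self._mesh_of_points([[2, 0, 0], [-2, 0, 0]])
        assert exposure_vector(_center("DON", [0, 0, 0], [1, 0, 0]), mesh) is None

    def test_out_of_range_undefined(self):
        mesh = self._mesh_of_points([[5, 0, 0]])
        assert exposure_vector(_center("DON", [0, 0, 0], [1, 0, 0]), mesh, 3.0) is None

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 3)) * 2
        mesh = self._mesh_of_points(pts)
        p = np.array([0.2, -0.1, 0.3])
        r = exposure_vector(_center("ACC", p, [0, 0, 1]), mesh, 3.0)
        diff = pts - p
        keep = np.linalg.norm(diff, axis=1) <= 3.0
        s = diff[keep].sum(axis=0)
        np.testing.assert_allclose(r, s / np.linalg.norm(s), atol=1e-12)


class TestFilterPseudocenters:
    def _mesh_at_angle(self, angle_deg, dist=2.0):
        """One surface vertex so that r makes the given angle with +z."""
        a = np.radians(angle_deg)
        vertex = dist * np.array([np.sin(a), 0.0, np.cos(a)])
        return SurfaceMesh(np.array([vertex]), np.array([[0, 0, 0]]))

    @pytest.mark.parametrize("kind,angle,kept", [
        ("DON", 99.0, True), ("DON", 101.0, False),
        ("ACC", 99.0, True), ("ACC", 101.0, False),
        ("ARO", 99.0, True), ("ARO", 101.0, False),
        ("DAC", 110.0, True), ("DAC", 119.0, True), ("DAC", 121.0, False),
    ])
    def test_cutoffs(self, kind, angle, kept):
        c = _center(kind, [0, 0, 0], [0, 0, 1.0])
        out = filter_pseudocenters([c], self._mesh_at_angle(angle))
        assert (len(out) == 1) == kept

    def test_ali_always_kept(self):
        c = Pseudocenter("ALI", [0, 0, 0], None, ("A", 1, "ALA"), np.array([0]))
        far_mesh = SurfaceMesh(np.array([[50.0, 0, 0]]), np.array([[0, 0, 0]]))
        assert len(filter_pseudocenters([c], far_mesh)) == 1

    def test_undefined_exposure_dropped(self):
        c = _center("DON", [0, 0, 0], [0, 0, 1.0])
        far_mesh = SurfaceMesh(np.array([[50.0, 0, 0]]), np.array([[0, 0, 0]]))
        assert filter_pseudocenters([c], far_mesh) == []

    def test_raising_cutoffs_keeps_superset(self):
        rng = np.random.default_rng(7)
        centers = [_center("DON", rng.normal(size=3),
                           rng.normal(size=3)) for _ in range(20)]
        mesh = SurfaceMesh(rng.normal(size=(30, 3)) * 2,
                           np.array([[0, 1, 2]]))
        tight = filter_pseudocenters(centers, mesh, cutoffs={"DON": 60})
        loose = filter_pseudocenters(centers, mesh, cutoffs={"DON": 140})
        ids_t = {id(c) for c in tight}
        ids_l = {id(c) for c in loose}
        assert ids_t <= ids_l


class TestAssignPseudoChannels:
    def _flat_mesh(self, verts):
        return SurfaceMesh(np.asarray(verts, float), np.array([[0, 1, 2]]))

    def test_nearest_center_wins(self):
        mesh = self._flat_mesh([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        acc = _center("ACC", [0, 2, 0], [0, 1, 0])
        don = _center("DON", [0, 2.5, 0], [0, 1, 0])
        out = assign_pseudo_channels(mesh, [acc, don], radius=3.0)
        np.testing.assert_array_equal(out[0], [0, 1, 0, 0])

    def test_null_beyond_radius(self):
        mesh = self._flat_mesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        acc = _center("ACC", [0, 3.2, 0], [0, 1, 0])
        out = assign_pseudo_channels(mesh, [acc], radius=3.0)
        np.testing.assert_array_equal(out[0], [0, 0, 0, 0])

    def test_dac_sets_both_bits(self):
        mesh = self._flat_mesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        dac = _center("DAC", [0, 1, 0], [0, 1, 0])
        out = assign_pseudo_channels(mesh, [dac], radius=3.0)
        np.testing.assert_array_equal(out[0], [1, 1, 0, 0])

    def test_row_sums_valid(self, toy_pipeline):
        pseudo = toy_pipeline["props"].pseudo
        sums = pseudo.sum(axis=1)
        assert set(np.unique(sums)) <= {0, 1, 2}
        two = pseudo[sums == 2]
        if len(two):
            assert np.all(two[:, [0, 1]] == 1)  # only DON+ACC from DAC


class TestHydrophobicity:
    def _mesh_one_vertex(self):
        return SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]))

    @pytest.mark.parametrize("q,expected", [(0.1, -1.0), (0.25, -1.0),
                                            (0.5, 1.0), (-0.5, 1.0)])
    def test_single_atom_binarization(self, q, expected):
        atoms = from_arrays([[2.0, 0, 0]], "C", partial_charge=q)
        out = assign_hydrophobicity(self._mesh_one_vertex(), atoms)
        np.testing.assert_allclose(out[0], expected)

    def test_equidistant_opposites_cancel(self):
        atoms = from_arrays([[2, 0, 0], [-2, 0, 0]], "C",
                            partial_charge=[0.1, 0.5])
        out = assign_hydrophobicity(self._mesh_one_vertex(), atoms)
        np.testing.assert_allclose(out[0], 0.0, atol=1e-12)

    def test_no_atom_in_range_gives_zero(self):
        atoms = from_arrays([[10, 0, 0]], "C")
        out = assign_hydrophobicity(self._mesh_one_vertex(), atoms)
        assert out[0] == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(
        st.floats(-3, 3), st.floats(-3, 3), st.floats(-3, 3),
        st.floats(-2, 2)), min_size=1, max_size=12))
    def test_bounded_for_any_input(self, rows):
        """Weighted average of +/-1 values stays in [-1, 1]."""
        coords = [r[:3] for r in rows]
        charges = [r[3] for r in rows]
        atoms = from_arrays(coords, "C", partial_charge=charges)
        out = assign_hydrophobicity(self._mesh_one_vertex(), atoms)
        assert np.all(np.abs(out) <= 1 + 1e-12)


class TestElectrostatics:
    def _mesh(self, verts):
        return SurfaceMesh(np.asarray(verts, float), np.array([[0, 1, 2]]))

    class _Fixed:
        def __init__(self, values):
            self.values = np.asarray(values, float)

        def potential(self, pts):
            return self.values

    @pytest.mark.parametrize("phi,expected", [(45.0, 1.0), (-15.0, -0.5),
                                              (30.0, 1.0), (0.0, 0.0)])
    def test_cap_and_normalize(self, phi, expected):
        mesh = self._mesh(np.zeros((3, 3)))
        out = assign_electrostatics(mesh, self._Fixed([phi] * 3))
        np.testing.assert_allclose(out, expected)

    def test_zero_charges_zero_potential(self):
        mesh = self._mesh([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        atoms = from_arrays([[3, 3, 3]], "C", partial_charge=0.0)
        out = assign_electrostatics(mesh, ScreenedCoulomb(atoms))
        np.testing.assert_allclose(out, 0.0)

    def test_screened_coulomb_sign_and_decay(self):
        atoms = from_arrays([[0, 0, 0]], "N", partial_charge=0.1)
        sc = ScreenedCoulomb(atoms, kappa=0.1, eps_r=4.0)
        near, far = sc.potential([[2, 0, 0], [8, 0, 0]])
        assert near > far > 0

    def test_dx_grid_roundtrip_and_coverage(self, tmp_path):
        nx = ny = nz = 4
        vals = np.arange(nx * ny * nz, dtype=float)
        lines = ["object 1 class gridpositions counts 4 4 4",
                 "origin 0.0 0.0 0.0",
                 "delta 1.0 0.0 0.0", "delta 0.0 1.0 0.0", "delta 0.0 0.0 1.0",
                 "object 2 class gridconnections counts 4 4 4",
                 f"object 3 class array type double rank 0 items {nx*ny*nz} data follows"]
        for i in range(0, len(vals), 3):
            lines.append(" ".join(f"{v:.1f}" for v in vals[i:i + 3]))
        path = tmp_path / "phi.dx"
        path.write_text("\n".join(lines) + "\n")
        grid = read_dx(path)
        assert grid.values.shape == (4, 4, 4)
        # trilinear interpolation at a grid node is exact
        np.testing.assert_allclose(grid.potential([[1, 2, 3]]),
                                   [vals.reshape(4, 4, 4)[1, 2, 3]])
        with pytest.raises(ValueError, match="cover"):
            grid.potential([[10, 0, 0]])


def test_rigid_invariance_of_all_properties(toy_pipeline):
    """Rotating atoms + mesh together leaves every vertex property unchanged."""
    from pocketsphere.properties import compute_vertex_properties

    atoms, mesh = toy_pipeline["atoms"], toy_pipeline["mesh"]
    props = toy_pipeline["props"]
    R = Rotation.from_euler("xyz", [0.5, -0.3, 1.7]).as_matrix()
    t = np.array([3.0, -7.0, 2.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        props_r = compute_vertex_properties(mesh.transformed(R, t),
                                            atoms.transformed(R, t))
    np.testing.assert_array_equal(props_r.pseudo, props.pseudo)
    np.testing.assert_allclose(props_r.hydrophobicity, props.hydrophobicity,
                               atol=1e-9)
    np.testing.assert_allclose(props_r.charge, props.charge, atol=1e-9)
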