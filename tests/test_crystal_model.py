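"""Crystal reading, symmetry expansion, molecule identification, dimers."""

import numpy as np
import pytest

import hopcrystal as hc
from hopcrystal import synthetic_data as sd
from hopcrystal.crystal_model import (
    CrystalStructure,
    Molecule,
    SymmetryOp,
    UnitCell,
    deduplicate_dimers,
    enumerate_dimers,
    identify_molecules,
    read_cif,
)
from hopcrystal.errors import FormatError

from conftest import random_rigid_motion


class TestUnitCell:
    def test_orthogonal_frac_to_cart(self):
        cell = UnitCell(10, 10, 10)
        assert np.allclose(cell.frac_to_cart, 10 * np.eye(3))

    def test_a_axis_length_preserved(self):
        cell = UnitCell(7.3, 8.1, 9.9, alpha=95, beta=101, gamma=112)
        assert np.linalg.norm(cell.frac_to_cart @ [1, 0, 0]) == pytest.approx(7.3)
        # b in the xy-plane by convention
        assert (cell.frac_to_cart @ [0, 1, 0])[2] == 0.0

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(-1, 5, 5)
        with pytest.raises(ValueError):
            UnitCell(5, 5, 5, alpha=0)


class TestSymmetryOp:
    def test_screw_axis_triplet(self):
        op = SymmetryOp.from_triplet("-x, y+1/2, -z+1/2")
        assert np.allclose(op.rotation, np.diag([-1, 1, -1]))
        assert np.allclose(op.translation, [0, 0.5, 0.5])

    def test_parsed_op_acts_like_string(self):
        # oracle: apply the op to test points and compare with the formula
        op = SymmetryOp.from_triplet("y, -x, z+1/4")
        for p in ([0.1, 0.2, 0.3], [0.7, 0.9, 0.5]):
            expect = np.array([p[1], -p[0], p[2] + 0.25])
            assert np.allclose(op.apply(np.array(p)), expect)

    def test_bad_triplet(self):
        from hopcrystal.errors import SymmetryError

        with pytest.raises(SymmetryError):
            SymmetryOp.from_triplet("not an op")


class TestReadCif:
    def test_one_atom_p1(self, tmp_path):
        path = tmp_path / "one.cif"
        path.write_text(
            "data_one\n"
            "_cell_length_a 10\n_cell_length_b 10\n_cell_length_c 10\n"
            "_cell_angle_alpha 90\n_cell_angle_beta 90\n_cell_angle_gamma 90\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "C1 C 0.5 0.5 0.5\n"
        )
        s = read_cif(path)
        cart = s.site_frac @ s.cell.frac_to_cart.T
        assert np.allclose(cart, [[5, 5, 5]])
        assert len(s.symmetry) == 1

    def test_round_trip(self, tmp_path, anthracene):
        struct = sd.make_stack_crystal(
            sd.StackSpec(template=anthracene, spacing=3.6, slip=1.5)
        )
        path = tmp_path / "stack.cif"
        sd.write_cif(struct, path)
        back = read_cif(path)
        m1, m2 = struct.cell.frac_to_cart, back.cell.frac_to_cart
        assert np.abs(m1 - m2).max() < 1e-6
        assert np.abs(struct.site_frac @ m1.T - back.site_frac @ m2.T).max() < 1e-6
        assert struct.site_elements == back.site_elements

    def test_missing_cell_is_format_error(self, tmp_path):
        path = tmp_path / "bad.cif"
        path.write_text("data_bad\n_cell_length_a 10\n")
        with pytest.raises(FormatError):
            read_cif(path)

    def test_partial_occupancy_rejected(self, tmp_path):
        path = tmp_path / "dis.cif"
        path.write_text(
            "data_dis\n"
            "_cell_length_a 10\n_cell_length_b 10\n_cell_length_c 10\n"
            "_cell_angle_alpha 90\n_cell_angle_beta 90\n_cell_angle_gamma 90\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "_atom_site_occupancy\n"
            "C1 C 0.5 0.5 0.5 0.5\n"
        )
        with pytest.raises(FormatError):
            read_cif(path)
        assert len(read_cif(path, keep_partial_occupancy=True).site_elements) == 1

    def test_spacegroup_label_expansion(self, tmp_path):
        path = tmp_path / "p21c.cif"
        path.write_text(
            "data_x\n"
            "_cell_length_a 8\n_cell_length_b 9\n_cell_length_c 10\n"
            "_cell_angle_alpha 90\n_cell_angle_beta 95\n_cell_angle_gamma 90\n"
            "_symmetry_space_group_name_H-M 'P 21/c'\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "C1 C 0.1 0.2 0.3\n"
        )
        s = read_cif(path)
        assert len(s.symmetry) == 4


class TestIdentifyMolecules:
    def test_isolated_atoms(self):
        s = CrystalStructure(
            cell=UnitCell(20, 20, 20),
            symmetry=[],
            site_elements=["C", "C"],
            site_frac=np.array([[0.1, 0.1, 0.1], [0.6, 0.6, 0.6]]),
        )
        out = identify_molecules(s)
        assert len(out.molecules) == 2
        assert all(m.n_atoms == 1 for m in out.molecules)

    def test_benzene_connectivity(self, benzene):
        s = CrystalStructure(
            cell=UnitCell(20, 20, 20),
            symmetry=[],
            site_elements=list(benzene.elements),
            site_frac=(benzene.coords + 10.0) / 20.0,
        )
        out = identify_molecules(s)
        assert len(out.molecules) == 1
        mol = out.molecules[0]
        assert mol.n_atoms == 12
        assert len(mol.bonds) == 12  # 6 CC + 6 CH

    def test_boundary_wrap_reassembly(self, benzene):
        # push the molecule across the cell boundary: fractional coords wrap
        frac = (benzene.coords + [19.0, 10.0, 10.0]) / 20.0
        s = CrystalStructure(
            cell=UnitCell(20, 20, 20),
            symmetry=[],
            site_elements=list(benzene.elements),
            site_frac=frac % 1.0,
        )
        out = identify_molecules(s)
        assert len(out.molecules) == 1
        mol = out.molecules[0]
        lengths = [np.linalg.norm(mol.coords[i] - mol.coords[j]) for i, j in mol.bonds]
        assert max(lengths) < 1.8

    def test_symmetry_expansion_counts(self, tmp_path, benzene):
        # inversion doubles the single asu molecule
        s = CrystalStructure(
            cell=UnitCell(20, 20, 20),
            symmetry=[
                hc.SymmetryOp.identity(),
                hc.SymmetryOp(rotation=-np.eye(3), translation=np.zeros(3)),
            ],
            site_elements=list(benzene.elements),
            site_frac=(benzene.coords + [5.0, 5.0, 5.0]) / 20.0,
        )
        out = identify_molecules(s)
        assert len(out.molecules) == 2


class TestEnumerateDimers:
    def test_isolated_molecule_no_dimers(self, benzene):
        s = identify_molecules(
            CrystalStructure(
                cell=UnitCell(50, 50, 50),
                symmetry=[],
                site_elements=list(benzene.elements),
                site_frac=(benzene.coords + 25.0) / 50.0,
            )
        )
        assert enumerate_dimers(s, cutoff=10.0) == []

    def test_1d_stack(self, stack_structure):
        pairs = enumerate_dimers(stack_structure, cutoff=5.0)
        assert len(pairs) == 1
        assert pairs[0].multiplicity == 2
        assert pairs[0].r == pytest.approx(3.5)

    def test_slip_distance(self, anthracene):
        s = hc.identify_molecules(
            sd.make_stack_crystal(sd.StackSpec(template=anthracene, spacing=3.5, slip=1.5))
        )
        pairs = enumerate_dimers(s, cutoff=5.0)
        assert len(pairs) == 1
        assert pairs[0].r == pytest.approx(np.hypot(3.5, 1.5))

    def test_herringbone_two_classes(self, anthracene):
        s = hc.identify_molecules(sd.make_herringbone_crystal(anthracene))
        merged = deduplicate_dimers(enumerate_dimers(s, cutoff=6.0))
        assert len(merged) == 2

    def test_matches_brute_force_supercell_scan(self, anthracene):
        """Oracle: explicit O(N²) pair scan over a 3×3×3 supercell."""
        s = hc.identify_molecules(
            sd.make_stack_crystal(sd.StackSpec(template=anthracene, spacing=3.3, slip=2.0))
        )
        cutoff = 8.0
        pairs = enumerate_dimers(s, cutoff=cutoff)
        total_from_enum = sum(p.multiplicity for p in pairs)

        m = s.cell.frac_to_cart
        centroids = []
        rng3 = (-3, -2, -1, 0, 1, 2, 3)  # covers the auto-grown search radius
        for i in rng3:
            for j in rng3:
                for k in rng3:
                    for mol in s.molecules:
                        centroids.append(mol.centroid + m @ np.array([i, j, k], float))
        centroids = np.array(centroids)
        home = s.molecules[0].centroid
        d = np.linalg.norm(centroids - home, axis=1)
        brute = int(((d > 1e-6) & (d <= cutoff)).sum())
        assert total_from_enum == brute

    def test_fingerprint_rigid_motion_invariance(self, anthracene, rng):
        base = sd.make_stack_crystal(sd.StackSpec(template=anthracene, spacing=3.5))
        pairs0 = enumerate_dimers(hc.identify_molecules(base), cutoff=5.0)
        rot, _trans = random_rigid_motion(rng)
        # rotate every molecule of the identified structure rigidly
        moved = hc.identify_molecules(base)
        moved.molecules = [m.transformed(rot, np.zeros(3)) for m in moved.molecules]
        # fingerprints are built from intermolecular distances only
        from hopcrystal.crystal_model import _pair_fingerprint

        fp0 = pairs0[0].fingerprint
        fp1 = _pair_fingerprint(
            moved.molecules[0],
            moved.molecules[0].translated(rot @ pairs0[0].r_vec),
        )
        assert np.abs(fp0 - fp1).max() < 1e-9


class TestDeduplicate:
    def test_translation_equivalents_merge(self, stack_structure):
        pairs = enumerate_dimers(stack_structure, cutoff=5.0)
        merged = deduplicate_dimers(pairs + pairs)
        assert len(merged) == 1
        assert merged[0].multiplicity == 4

    def test_swap_invariance(self, anthracene):
        from hopcrystal.crystal_model import _pair_fingerprint

        a = anthracene
        b = anthracene.translated([0.7, 0.3, 3.5])
        assert np.allclose(_pair_fingerprint(a, b), _pair_fingerprint(b, a))
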