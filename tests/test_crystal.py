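"""Periodic model: coordinate transforms, symmetry expansion, supercells,
molecule perception."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import embedshield as es
from embedshield.crystal import (
    Atom,
    ClashError,
    CrystalError,
    LatticeCell,
    MolecularCrystal,
    SymmetryOp,
    read_cif,
    write_xyz,
)


def metric_tensor(cell: LatticeCell) -> np.ndarray:
    """Independent oracle: G_ij = a_i·a_j from the textbook closed form."""
    al, be, ga = np.radians([cell.alpha, cell.beta, cell.gamma])
    a, b, c = cell.a, cell.b, cell.c
    return np.array(
        [
            [a * a, a * b * np.cos(ga), a * c * np.cos(be)],
            [a * b * np.cos(ga), b * b, b * c * np.cos(al)],
            [a * c * np.cos(be), b * c * np.cos(al), c * c],
        ]
    )


class TestLatticeCell:
    def test_orthogonal_cell_maps_fractions_to_lengths(self):
        cell = LatticeCell(10, 10, 10)
        assert np.allclose(cell.frac_to_cart([0.5, 0.5, 0.5]), [5, 5, 5])
        assert np.allclose(cell.frac_to_cart([0, 0, 0]), [0, 0, 0])

    def test_monoclinic_matches_metric_tensor(self):
        cell = LatticeCell(5, 6, 7, beta=100)
        G = metric_tensor(cell)
        # lengths and mutual angles of the lattice vectors against the metric
        M = cell.matrix
        assert np.allclose(M.T @ M, G, atol=1e-10)
        assert math.isclose(np.linalg.norm(cell.frac_to_cart([1, 0, 0])), 5)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(CrystalError):
            LatticeCell(5, 6, 7, alpha=10, beta=10, gamma=179)
        with pytest.raises(CrystalError):
            LatticeCell(-1, 6, 7)
        with pytest.raises(CrystalError):
            LatticeCell(5, 6, 7, gamma=180)

    @given(
        st.tuples(
            st.floats(2, 20), st.floats(2, 20), st.floats(2, 20),
            st.floats(60, 120), st.floats(60, 120), st.floats(60, 120),
        ),
        st.tuples(st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_frac_cart_roundtrip(self, params, frac):
        try:
            cell = LatticeCell(*params)
        except CrystalError:
            return  # invalid angle combination; nothing to round-trip
        back = cell.cart_to_frac(cell.frac_to_cart(np.array(frac)))
        assert np.allclose(back, frac, atol=1e-10)

    def test_convention_a_along_x_b_in_xy(self):
        cell = LatticeCell(5, 6, 7, 80, 95, 105)
        M = cell.matrix
        assert M[1, 0] == M[2, 0] == 0.0 and M[2, 1] == 0.0


class TestSymmetryOp:
    def test_screw_axis_image(self):
        op = SymmetryOp.from_xyz("-x, y+1/2, -z")
        img = op.apply(np.array([0.1, 0.1, 0.1]))
        assert np.allclose(img % 1.0, [0.9, 0.6, 0.9])

    def test_translation_reduced_and_det_checked(self):
        op = SymmetryOp(np.eye(3), [1.25, -0.5, 0.0])
        assert np.allclose(op.translation, [0.25, 0.5, 0.0])
        with pytest.raises(CrystalError):
            SymmetryOp(np.diag([2.0, 1.0, 1.0]), np.zeros(3))


class TestExpandSymmetry:
    def test_p1_returns_the_asymmetric_unit(self, p1_crystal):
        mols = es.expand_symmetry(p1_crystal)
        assert len(mols) == 1
        assert len(mols[0]) == len(p1_crystal.asym_atoms)

    def test_p21_doubles_the_contents(self, p21_crystal):
        mols = es.expand_symmetry(p21_crystal)
        assert len(mols) == 2
        assert all(m.centroid_frac.min() >= 0 and m.centroid_frac.max() < 1 for m in mols)

    def test_p21c_four_general_positions(self):
        """Brute-force oracle: 4 ops on a general position give 4 distinct images."""
        ops = tuple(
            SymmetryOp.from_xyz(s)
            for s in ("x,y,z", "-x,y+1/2,-z+1/2", "-x,-y,-z", "x,-y+1/2,z+1/2")
        )
        cell = LatticeCell(8, 9, 10, beta=95)
        atoms = (Atom("He", (0.13, 0.21, 0.34), site_id=0),)
        mols = es.expand_symmetry(MolecularCrystal(cell, ops, atoms))
        assert len(mols) == 4
        centroids = {tuple(np.round(m.centroid_frac % 1.0, 6)) for m in mols}
        assert len(centroids) == 4

    def test_special_position_duplicates_merged(self):
        # atom on the inversion centre: -x,-y,-z maps it onto itself
        ops = (SymmetryOp.identity(), SymmetryOp.from_xyz("-x,-y,-z"))
        atoms = (Atom("He", (0.0, 0.0, 0.0), site_id=0),)
        mols = es.expand_symmetry(MolecularCrystal(LatticeCell(6, 6, 6), ops, atoms))
        assert len(mols) == 1

    def test_overlapping_molecules_flagged(self):
        ops = (SymmetryOp.identity(), SymmetryOp.from_xyz("-x,-y,-z"))
        # just off the inversion centre: the image lands 0.12 A away
        atoms = (Atom("He", (0.005, 0.0, 0.0), site_id=0),)
        with pytest.raises(ClashError):
            es.expand_symmetry(MolecularCrystal(LatticeCell(12, 12, 12), ops, atoms))


class TestBuildSupercell:
    def test_n1_is_the_unit_cell(self, p21_crystal):
        atoms = es.build_supercell(p21_crystal, 1)
        assert len(atoms) == 6
        assert all(a.cell_offset == (0, 0, 0) for a in atoms)

    def test_single_site_9cube(self):
        cry = MolecularCrystal(
            LatticeCell(5, 5, 5), (SymmetryOp.identity(),),
            (Atom("He", (0.5, 0.5, 0.5), site_id=0),),
        )
        atoms = es.build_supercell(cry, 9)
        assert len(atoms) == 729
        offsets = {a.cell_offset for a in atoms}
        assert len(offsets) == 729
        assert all(max(abs(o) for o in off) <= 4 for off in offsets)

    def test_two_molecules_n3_enumeration(self, p21_crystal):
        """Enumeration oracle: 2 molecules x 3 atoms x 27 cells."""
        atoms = es.build_supercell(p21_crystal, 3)
        assert len(atoms) == 162
        by_cell = {}
        for a in atoms:
            by_cell.setdefault(a.cell_offset, []).append(a.site_id)
        assert len(by_cell) == 27
        ref = sorted(by_cell[(0, 0, 0)])
        assert all(sorted(v) == ref for v in by_cell.values())

    def test_even_n_rejected(self, p1_crystal):
        with pytest.raises(CrystalError):
            es.build_supercell(p1_crystal, 2)


class TestPerceiveMolecules:
    def test_distant_atoms_are_separate_molecules(self):
        cell = LatticeCell(30, 30, 30)
        atoms = [
            Atom("He", (0.1, 0.1, 0.1), site_id=0),
            Atom("He", (0.1 + 10 / 30, 0.1, 0.1), site_id=1),
        ]
        assert len(es.perceive_molecules(atoms, cell)) == 2

    def test_water_from_covalent_radii(self):
        cell = LatticeCell(20, 20, 20)
        xyz = np.array([[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        frac = cell.cart_to_frac(xyz)
        atoms = [
            Atom(el, tuple(f), site_id=i)
            for i, (el, f) in enumerate(zip("OHH", frac))
        ]
        mols = es.perceive_molecules(atoms, cell)
        assert len(mols) == 1 and len(mols[0]) == 3

    def test_diatomic_unwrapped_across_boundary(self):
        cell = LatticeCell(10, 10, 10)
        atoms = [
            Atom("C", (0.98, 0.1, 0.1), site_id=0),
            Atom("C", (0.02, 0.1, 0.1), site_id=1),
        ]
        mols = es.perceive_molecules(atoms, cell, periodic=True)
        assert len(mols) == 1
        d = np.linalg.norm(np.diff(mols[0].cart_coords, axis=0))
        assert math.isclose(d, 0.4, abs_tol=1e-9)  # minimum-image contact

    def test_unknown_element_rejected(self):
        with pytest.raises(CrystalError):
            Atom("Qq", (0, 0, 0), site_id=0)

    def test_expand_then_perceive_counts_ops_times_molecules(self, p21_crystal):
        mols = es.expand_symmetry(p21_crystal)
        all_atoms = [a for m in mols for a in m.atoms]
        re_perceived = es.perceive_molecules(all_atoms, p21_crystal.cell, periodic=True)
        assert len(re_perceived) == len(p21_crystal.ops) * 1


class TestCifIO:
    CIF = """data_toy
_cell_length_a 6.0
_cell_length_b 7.0
_cell_length_c 8.0
_cell_angle_alpha 90.0
_cell_angle_beta 100.0
_cell_angle_gamma 90.0
loop_
_space_group_symop_operation_xyz
'x, y, z'
'-x, y+1/2, -z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
O1 O 0.30 0.25 0.20
H1 H 0.45 0.25 0.25
H2 H 0.25 0.37 0.25
"""

    def test_read_cif_both_symop_dialects(self, tmp_path):
        p = tmp_path / "toy.cif"
        p.write_text(self.CIF)
        cry = read_cif(p)
        assert cry.cell.beta == 100.0
        assert len(cry.ops) == 2 and len(cry.asym_atoms) == 3
        legacy = self.CIF.replace(
            "_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz"
        )
        p2 = tmp_path / "legacy.cif"
        p2.write_text(legacy)
        cry2 = read_cif(p2)
        assert len(cry2.ops) == 2
        assert np.allclose(
            [a.frac for a in cry.asym_atoms], [a.frac for a in cry2.asym_atoms]
        )

    def test_xyz_export_counts_and_comment(self, p21_crystal):
        mols = es.expand_symmetry(p21_crystal)
        text = write_xyz(mols)
        lines = text.splitlines()
        assert lines[0] == "6"
        assert len(lines) == 8
        assert "mol_id" in lines[1]
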