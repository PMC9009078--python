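"""Engine contract: deck writing, point-charge files, output parsing,
mock shielding backend."""

from pathlib import Path

import numpy as np
import pytest

import embedshield as es
from embedshield.cluster import PointCharge
from embedshield.embedding import ANGSTROM_PER_BOHR
from embedshield.qm_io import (
    MethodSpec,
    QMIOError,
    ShieldingTable,
    parse_shieldings,
    write_shielding_output,
)

DATA = Path(__file__).parent / "data"


class TestMethodSpec:
    def test_unknown_method_rejected(self):
        with pytest.raises(QMIOError):
            MethodSpec(method="CCSD(T)")

    def test_mp2_takes_no_dispersion(self):
        with pytest.raises(QMIOError):
            MethodSpec(method="MP2", dispersion=True)


class TestWriteNmrInput:
    def test_deterministic_bytes(self, p21_cluster):
        spec = MethodSpec(method="B3LYP")
        assert es.write_nmr_input(p21_cluster, spec) == es.write_nmr_input(
            p21_cluster, spec
        )

    def test_pbe_has_no_pno_keywords(self, p21_cluster):
        deck = es.write_nmr_input(p21_cluster, MethodSpec(method="PBE"))
        assert "PNO" not in deck and "%mp2" not in deck
        assert deck.startswith("! PBE D3BJ")

    def test_fragment_tags_and_bases(self, p21_cluster):
        deck = es.write_nmr_input(p21_cluster, MethodSpec(method="B3LYP"))
        lines = deck.splitlines()
        qm1_lines = [l for l in lines if "(1)" in l]
        qm2_lines = [l for l in lines if "(2)" in l]
        assert len(qm1_lines) == len(p21_cluster.qm1)
        assert len(qm2_lines) == sum(len(m) for m in p21_cluster.qm2)
        assert all('"pcSseg-3"' in l for l in qm1_lines)
        assert all('"def2-TZVP"' in l for l in qm2_lines)
        # shieldings requested for the central-molecule nuclei only
        assert "Nuclei = 0,1,2 { shift }" in deck

    def test_multilevel_deck_matches_golden_file(self, p21_cluster):
        deck = es.write_nmr_input(
            p21_cluster, MethodSpec(method="MP2", dispersion=False), pc_filename="toy.pc"
        )
        assert deck == (DATA / "golden_mp2_deck.inp").read_text()


class TestPointChargeFile:
    def test_empty(self):
        assert es.write_pointcharge_file([]) == "0\n"

    def test_single_charge_formatting(self):
        pc = PointCharge(q=-0.5, pos=(1.0, 2.0, 3.0), site_id=0)
        assert (
            es.write_pointcharge_file([pc])
            == "1\n-0.500000 1.000000 2.000000 3.000000\n"
        )

    def test_count_line_matches_field(self, p21_cluster):
        text = es.write_pointcharge_file(p21_cluster.mm)
        lines = text.splitlines()
        assert int(lines[0]) == len(p21_cluster.mm)
        assert len(lines) == len(p21_cluster.mm) + 1


class TestParseShieldings:
    def test_roundtrip_on_mock_output(self, p21_cluster, p21_params):
        charges = es.ChargeSet(dict(enumerate(p21_params.charges)))
        table = es.mock_shieldings(p21_cluster, charges, system="toy", method="MOCK")
        text = write_shielding_output(table)
        back = parse_shieldings(text, system="toy", method="MOCK")
        assert back == table or np.allclose(
            back.frame.sigma_ppm, table.frame.sigma_ppm, atol=1e-6
        )
        assert list(back.frame.nucleus) == list(table.frame.nucleus)

    def test_empty_text_is_an_error(self):
        with pytest.raises(QMIOError, match="no nucleus"):
            parse_shieldings("")

    def test_duplicate_nucleus_rejected(self):
        text = (
            " Nucleus 0H :\n   Isotropic shielding (ppm) : 30.0\n"
            " Nucleus 0H :\n   Isotropic shielding (ppm) : 31.0\n"
        )
        with pytest.raises(QMIOError, match="duplicate"):
            parse_shieldings(text)

    def test_missing_value_names_the_nucleus(self):
        with pytest.raises(QMIOError, match="H0"):
            parse_shieldings(" Nucleus 0H :\n   nothing here\n")


class TestShieldingTable:
    def test_duplicate_key_rejected(self):
        with pytest.raises(QMIOError, match="duplicate"):
            ShieldingTable.from_records(
                [("s", "H1", "H", "PBE", 30.0), ("s", "H1", "H", "PBE", 31.0)]
            )

    def test_non_finite_rejected(self):
        with pytest.raises(QMIOError):
            ShieldingTable.from_records([("s", "H1", "H", "PBE", float("nan"))])

    def test_csv_roundtrip(self, tmp_path):
        t = ShieldingTable.from_records(
            [("s", "H1", "H", "PBE", 30.0), ("s", "C2", "C", "PBE", 150.0)]
        )
        t.to_csv(tmp_path / "t.csv")
        assert ShieldingTable.from_csv(tmp_path / "t.csv") == t


class TestMockShieldings:
    def test_no_environment_gives_baselines(self, p21_crystal):
        cluster = es.build_cluster(p21_crystal, cutoff=0.0, n=3)
        table = es.mock_shieldings(cluster)
        assert np.allclose(table.frame.sigma_ppm, [280.0, 30.0, 30.0])

    def test_single_unit_charge_closed_form(self, p21_crystal):
        """One charge at 1 bohr from an H: sigma = 30 + c_H * 1."""
        from embedshield.qm_io import MOCK_RESPONSE

        qm1 = es.expand_symmetry(p21_crystal)[0]
        h_pos = qm1.cart_coords[1]
        pc = PointCharge(
            q=1.0, pos=tuple(h_pos + [ANGSTROM_PER_BOHR, 0, 0]), site_id=0
        )
        cluster = es.ClusterModel(
            qm1=qm1, qm2=(), mm=(pc,), crystal=p21_crystal
        )
        table = es.mock_shieldings(cluster)
        sigma_h = table.frame.set_index("nucleus").sigma_ppm["H1"]
        d_o = np.linalg.norm(np.asarray(pc.pos) - qm1.cart_coords[0]) / ANGSTROM_PER_BOHR
        d_h2 = np.linalg.norm(np.asarray(pc.pos) - qm1.cart_coords[2]) / ANGSTROM_PER_BOHR
        assert np.isclose(sigma_h, 30.0 + MOCK_RESPONSE["H"] * 1.0)
        assert np.isclose(
            table.frame.set_index("nucleus").sigma_ppm["O0"],
            280.0 + 80.0 / d_o,
        )
        assert np.isclose(
            table.frame.set_index("nucleus").sigma_ppm["H2"],
            30.0 + MOCK_RESPONSE["H"] / d_h2,
        )

    def test_mirror_symmetric_charges_give_equal_sigmas(self, p21_crystal):
        """Symmetry oracle: charges mirror-symmetric about the HH bisector plane."""
        qm1 = es.expand_symmetry(p21_crystal)[0]
        h1, h2 = qm1.cart_coords[1], qm1.cart_coords[2]
        mid = (h1 + h2) / 2
        axis = (h2 - h1) / np.linalg.norm(h2 - h1)
        off = 2.5 * axis
        mm = (
            PointCharge(q=0.3, pos=tuple(mid + off), site_id=0),
            PointCharge(q=0.3, pos=tuple(mid - off), site_id=0),
        )
        cluster = es.ClusterModel(qm1=qm1, qm2=(), mm=mm, crystal=p21_crystal)
        t = es.mock_shieldings(cluster).frame.set_index("nucleus").sigma_ppm
        assert np.isclose(t["H1"], t["H2"], atol=1e-10)

    def test_rigid_motion_invariance(self, p21_cluster, p21_params):
        """Translating/rotating the whole cluster leaves sigmas unchanged."""
        charges = es.ChargeSet(dict(enumerate(p21_params.charges)))
        ref = es.mock_shieldings(p21_cluster, charges)
        # translation is exercised via the MM/QM distance structure: shift
        # every Cartesian ingredient by the same vector
        shift = np.array([3.0, -2.0, 1.0])
        qm1 = p21_cluster.qm1
        from dataclasses import replace as drep

        cell = p21_cluster.crystal.cell
        fshift = cell.cart_to_frac(shift)
        moved_qm1 = es.Molecule(
            tuple(
                drep(a, frac=tuple(np.asarray(a.frac) + fshift)) for a in qm1.atoms
            ),
            cell,
            qm1.mol_id,
        )
        moved_qm2 = tuple(
            es.Molecule(
                tuple(
                    drep(a, frac=tuple(np.asarray(a.frac) + fshift)) for a in m.atoms
                ),
                cell,
                m.mol_id,
            )
            for m in p21_cluster.qm2
        )
        moved_mm = tuple(
            drep(pc, pos=tuple(np.asarray(pc.pos) + shift)) for pc in p21_cluster.mm
        )
        moved = es.ClusterModel(
            qm1=moved_qm1, qm2=moved_qm2, mm=moved_mm, crystal=p21_cluster.crystal
        )
        out = es.mock_shieldings(moved, charges)
        assert np.allclose(out.frame.sigma_ppm, ref.frame.sigma_ppm, atol=1e-9)
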