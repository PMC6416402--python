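import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conflock.structure import (AtomRecord, EmptyStructureError, PDBParseError,
                                ResidueId, StructureModel, center_of_mass,
                                com_distance, element_mass, read_pdb, rmsd,
                                rmsd_coords, write_pdb)
from conflock.synthetic import synthetic_dissociation_trajectory


def _atom(serial, name, element, chain, seq, xyz, resname="ALA", occ=1.0):
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, chain_id=chain, residue_seq=seq,
                      coords=np.asarray(xyz, float), mass=element_mass(element),
                      occupancy=occ)


class TestResidueId:
    def test_label_round_trip(self):
        rid = ResidueId("A", 149, "ILE")
        assert rid.label == "Ile149A"
        assert ResidueId.from_label("Ile149A") == rid

    def test_ordering_by_chain_then_seq(self):
        assert ResidueId("A", 149, "ILE") < ResidueId("B", 9, "LYS")
        assert ResidueId("A", 9, "LYS") < ResidueId("A", 149, "ILE")

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            ResidueId.from_label("nonsense")


class TestReadPdb:
    def test_two_chain_fixture(self, two_chain_pdb):
        s = read_pdb(two_chain_pdb)
        assert s.n_atoms == 4
        assert s.chain_ids() == ["A", "B"]
        assert s.pdb_id == "TOY1"
        assert s.atoms[0].name == "N" and s.atoms[0].element == "N"

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM      1  N   GLY A   1       0.000   0.000   0.000\n"
                     "ATOM      2  CA  GLY A   1        bad.   0.000   0.000\n")
        with pytest.raises(PDBParseError, match="line 2"):
            read_pdb(p)

    def test_no_atoms_is_empty_structure(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_pdb(p)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  N   GLY A   1       1.000   0.000   0.000  1.00  0.00           N\n")
        s = read_pdb(p)
        ca = [a for a in s.atoms if a.name == "CA"]
        assert len(ca) == 1 and ca[0].coords[0] == pytest.approx(9.0)

    def test_hetatm_flagged_and_excluded_from_chains(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2 CU    CU A 200       5.000   5.000   5.000  1.00  0.00          CU\n")
        s = read_pdb(p)
        het = [a for a in s.atoms if a.is_hetatm]
        assert len(het) == 1 and het[0].element == "CU"
        assert all(not a.is_hetatm for a in s.chain_atoms("A"))


class TestRoundTrip:
    def test_write_read_preserves_atoms_and_coords(self, tmp_path, interface_structure):
        out = tmp_path / "synthetic_interface.pdb"
        write_pdb(interface_structure, out)
        back = read_pdb(out)
        assert back.n_atoms == interface_structure.n_atoms
        assert [a.name for a in back.atoms] == [a.name for a in interface_structure.atoms]
        assert back.chain_ids() == interface_structure.chain_ids()
        np.testing.assert_allclose(back.frames, interface_structure.frames, atol=1e-3)

    def test_multi_model_round_trip(self, tmp_path):
        traj = synthetic_dissociation_trajectory(n_frames=5)
        out = tmp_path / "synthetic_traj.pdb"
        write_pdb(traj, out)
        back = read_pdb(out)
        assert back.n_frames == 5
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)

    def test_against_biopython_parser(self, tmp_path, interface_structure):
        """Independent cross-check: Bio.PDB reads back what write_pdb emits."""
        Bio = pytest.importorskip("Bio.PDB")
        out = tmp_path / "synthetic_interface.pdb"
        write_pdb(interface_structure, out)
        parser = Bio.PDBParser(QUIET=True)
        model = parser.get_structure("x", str(out))[0]
        bio_atoms = list(model.get_atoms())
        assert len(bio_atoms) == interface_structure.n_atoms
        bio_xyz = np.asarray([a.coord for a in bio_atoms])
        np.testing.assert_allclose(
            np.sort(bio_xyz, axis=0),
            np.sort(interface_structure.frames[0], axis=0), atol=1e-3)


class TestCenterOfMass:
    def test_equal_mass_midpoint_in_nm(self):
        atoms = [_atom(1, "H1", "H", "A", 1, (0, 0, 0)),
                 _atom(2, "H2", "H", "A", 1, (2, 0, 0))]
        s = StructureModel(atoms)
        np.testing.assert_allclose(center_of_mass(s, "A"), [0.1, 0, 0], atol=1e-12)

    def test_single_atom_is_own_position(self):
        s = StructureModel([_atom(1, "CA", "C", "A", 1, (3.0, -1.0, 2.0))])
        np.testing.assert_allclose(center_of_mass(s, "A"), [0.3, -0.1, 0.2])

    def test_mass_weighted_mean_oracle(self):
        # independent hand arithmetic: C at 0, N at (1,0,0) A, O at (0,2,0) A
        mc, mn, mo = 12.011, 14.007, 15.999
        atoms = [_atom(1, "C", "C", "A", 1, (0, 0, 0)),
                 _atom(2, "N", "N", "A", 1, (1, 0, 0)),
                 _atom(3, "O", "O", "A", 1, (0, 2, 0))]
        s = StructureModel(atoms)
        expected = np.array([mn * 1.0, mo * 2.0, 0.0]) / (mc + mn + mo) / 10.0
        np.testing.assert_allclose(center_of_mass(s, "A"), expected, atol=1e-12)

    def test_unknown_chain_raises(self, two_chain_pdb):
        s = read_pdb(two_chain_pdb)
        with pytest.raises(KeyError):
            center_of_mass(s, "Z")


class TestComDistance:
    def _dimer(self, shift_nm):
        a = [_atom(1, "CA", "C", "A", 1, (0, 0, 0)),
             _atom(2, "N", "N", "A", 1, (1.5, 1.0, 0))]
        b = [_atom(3, "CA", "C", "B", 1, (0 + shift_nm[0] * 10, shift_nm[1] * 10, shift_nm[2] * 10)),
             _atom(4, "N", "N", "B", 1, (1.5 + shift_nm[0] * 10, 1.0 + shift_nm[1] * 10, shift_nm[2] * 10))]
        return StructureModel(a + b)

    def test_translated_copy(self):
        s = self._dimer((4.01, 0, 0))
        assert com_distance(s, "A", "B") == pytest.approx(4.01, abs=1e-12)

    def test_identical_chains_zero(self):
        s = self._dimer((0, 0, 0))
        assert com_distance(s, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_translation_invariant(self):
        s = self._dimer((1.0, -2.0, 0.5))
        d = com_distance(s, "A", "B")
        assert com_distance(s, "B", "A") == pytest.approx(d)
        s.frames = s.frames + np.array([7.0, -3.0, 11.0])
        assert com_distance(s, "A", "B") == pytest.approx(d)

    def test_dissociation_trajectory_endpoints(self):
        traj = synthetic_dissociation_trajectory(n_frames=11)
        assert com_distance(traj, "A", "B", 0) == pytest.approx(2.82, abs=1e-6)
        assert com_distance(traj, "A", "B", 10) == pytest.approx(6.83, abs=1e-6)
        dists = [com_distance(traj, "A", "B", f) for f in range(11)]
        assert np.all(np.diff(dists) > 0)


class TestRmsd:
    def test_identical_frames_zero(self):
        traj = synthetic_dissociation_trajectory(n_frames=3)
        assert rmsd(traj, 0, 0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(8, 3)) * 5.0
        rot = Rotation.random(random_state=seed)
        mob = rot.apply(ref) + rng.normal(size=3) * 10.0
        assert rmsd_coords(ref, mob, fit=True) == pytest.approx(0.0, abs=1e-9)

    def test_unfitted_single_displacement_closed_form(self):
        ref = np.zeros((5, 3))
        ref[:, 0] = np.arange(5) * 100.0  # spread out, irrelevant without fit
        mob = ref.copy()
        mob[2, 1] += 5.0  # 0.5 nm in A
        atoms = [_atom(i + 1, "CA", "C", "A", i + 1, ref[i]) for i in range(5)]
        s = StructureModel(atoms, np.stack([ref, mob]))
        assert rmsd(s, 1, 0, fit=False) == pytest.approx(np.sqrt(0.25 / 5), abs=1e-6)

    def test_mismatched_selection_shapes_raise(self):
        with pytest.raises(ValueError):
            rmsd_coords(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_degenerate_fit_falls_back_with_warning(self):
        ref = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])  # collinear
        mob = ref + np.array([1.0, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            val = rmsd_coords(ref, mob, fit=True)
        assert val == pytest.approx(1.0)
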