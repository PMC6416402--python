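import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conflock.contacts import (ContactCriteria, ContactKind, HBondCriteria,
                               HydrophobicCriteria, SaltBridgeCriteria,
                               detect_hydrogen_bonds,
                               detect_hydrophobic_contacts,
                               detect_salt_bridges, interface_census)
from conflock.structure import AtomRecord, StructureModel, element_mass


def _atom(serial, name, element, chain, seq, xyz, resname):
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, chain_id=chain, residue_seq=seq,
                      coords=np.asarray(xyz, float), mass=element_mass(element))


def _hbond_fixture(distance):
    """Backbone O (chain A) facing backbone N (chain B) at the given distance."""
    return StructureModel([
        _atom(1, "O", "O", "A", 10, (0, 0, 0), "GLY"),
        _atom(2, "N", "N", "B", 20, (distance, 0, 0), "ALA"),
    ])


def _cb_fixture(distance):
    return StructureModel([
        _atom(1, "CB", "C", "A", 1, (0, 0, 0), "ALA"),
        _atom(2, "CB", "C", "B", 2, (distance, 0, 0), "ALA"),
    ])


def _salt_fixture(dist_A):
    return StructureModel([
        _atom(1, "OD1", "O", "A", 11, (0, 0.6, 0), "ASP"),
        _atom(2, "OD2", "O", "A", 11, (0, -0.6, 0), "ASP"),
        _atom(3, "NZ", "N", "B", 9, (dist_A, 0, 0), "LYS"),
    ])


class TestHydrogenBonds:
    def test_backbone_pair_within_cutoff(self):
        recs = detect_hydrogen_bonds(_hbond_fixture(2.9), "A", "B")
        assert len(recs) == 1
        rec = recs[0]
        assert rec.kind == ContactKind.HYDROGEN_BOND
        assert rec.distance == pytest.approx(2.9)
        assert rec.residue_a.chain_id == "A" and rec.residue_b.chain_id == "B"

    def test_beyond_cutoff_empty(self):
        assert detect_hydrogen_bonds(_hbond_fixture(4.0), "A", "B") == []

    def test_angle_criterion_with_explicit_hydrogen(self):
        # H on the donor pointing away from the acceptor: D-H...A angle ~ 0
        s = StructureModel([
            _atom(1, "O", "O", "A", 10, (0, 0, 0), "GLY"),
            _atom(2, "N", "N", "B", 20, (2.9, 0, 0), "ALA"),
            _atom(3, "H", "H", "B", 20, (3.9, 0, 0), "ALA"),
        ])
        assert detect_hydrogen_bonds(s, "A", "B") == []

    def test_interface_pairs_recovered(self, interface_structure):
        recs = detect_hydrogen_bonds(interface_structure, "A", "B")
        pairs = {frozenset((r.residue_a.label, r.residue_b.label)) for r in recs}
        assert pairs == {frozenset(p.split("-")) for p in
                         ("Ile149A-Gly49B", "Ile149A-Gly112B",
                          "Ile149B-Gly49A", "Ile149B-Gly112A")}


class TestHydrophobicContacts:
    def test_cb_pair_within_cutoff(self):
        recs = detect_hydrophobic_contacts(_cb_fixture(3.5), "A", "B")
        assert len(recs) == 1

    def test_beyond_cutoff_empty(self):
        assert detect_hydrophobic_contacts(_cb_fixture(4.5), "A", "B") == []

    def test_atom_vs_residue_pair_counts(self):
        # 3 atom contacts within one residue pair
        atoms = [_atom(1, "CB", "C", "A", 1, (0, 0, 0), "LEU"),
                 _atom(2, "CG", "C", "A", 1, (0, 7, 0), "LEU"),
                 _atom(3, "CD1", "C", "A", 1, (0, 14, 0), "LEU"),
                 _atom(4, "CB", "C", "B", 2, (3.5, 0, 0), "LEU"),
                 _atom(5, "CG", "C", "B", 2, (3.5, 7, 0), "LEU"),
                 _atom(6, "CD1", "C", "B", 2, (3.5, 14, 0), "LEU")]
        census = interface_census(StructureModel(atoms), "A", "B")
        assert census.n_hydrophobic_atom_contacts == 3
        assert census.n_hydrophobic_residue_pairs == 1

    def test_matches_brute_force_oracle(self):
        """Random C-atom cloud: detector agrees with an all-pairs scan."""
        rng = np.random.default_rng(42)
        atoms = []
        for i in range(15):
            atoms.append(_atom(i + 1, "CB", "C", "A", i + 1,
                               rng.uniform(0, 15, 3), "ALA"))
        for j in range(15):
            atoms.append(_atom(100 + j, "CB", "C", "B", j + 1,
                               rng.uniform(0, 15, 3), "ALA"))
        s = StructureModel(atoms)
        recs = detect_hydrophobic_contacts(s, "A", "B")
        expected = 0
        for a in atoms[:15]:
            for b in atoms[15:]:
                if np.linalg.norm(a.coords - b.coords) <= 3.90:
                    expected += 1
        assert len(recs) == expected


class TestSaltBridges:
    def test_close_pair_detected(self):
        recs = detect_salt_bridges(_salt_fixture(3.5), "A", "B")
        assert len(recs) == 1
        assert recs[0].kind == ContactKind.SALT_BRIDGE

    def test_beyond_cutoff_excluded(self):
        assert detect_salt_bridges(_salt_fixture(6.5), "A", "B") == []

    def test_interface_asp_lys_beyond_cutoff(self, interface_structure):
        """The only inter-chain charged pair sits past 0.6 nm: no bridge."""
        assert detect_salt_bridges(interface_structure, "A", "B") == []


class TestCensus:
    def test_empty_interface_all_zero(self):
        atoms = [_atom(1, "CB", "C", "A", 1, (0, 0, 0), "ALA"),
                 _atom(2, "CB", "C", "B", 1, (50, 0, 0), "ALA")]
        census = interface_census(StructureModel(atoms), "A", "B")
        assert census.summary() == {"n_hbond_pairs": 0,
                                    "n_hydrophobic_atom_contacts": 0,
                                    "n_hydrophobic_residue_pairs": 0,
                                    "n_salt_bridges": 0}

    def test_composed_hand_fixture(self):
        atoms = [
            _atom(1, "O", "O", "A", 1, (0, 0, 0), "GLY"),
            _atom(2, "N", "N", "B", 1, (2.9, 0, 0), "ALA"),
            _atom(3, "O", "O", "A", 2, (0, 20, 0), "GLY"),
            _atom(4, "N", "N", "B", 2, (3.0, 20, 0), "ALA"),
            _atom(5, "CB", "C", "A", 3, (0, 40, 0), "ALA"),
            _atom(6, "CB", "C", "B", 3, (3.5, 40, 0), "ALA"),
            _atom(7, "CB", "C", "A", 4, (0, 60, 0), "VAL"),
            _atom(8, "CG1", "C", "B", 4, (3.2, 60, 0), "VAL"),
            _atom(9, "CG2", "C", "B", 4, (-3.2, 60, 0), "VAL"),
        ]
        census = interface_census(StructureModel(atoms), "A", "B")
        assert census.n_hbond_pairs == 2
        assert census.n_hydrophobic_atom_contacts == 3
        assert census.n_hydrophobic_residue_pairs == 2

    def test_interface_structure_census(self, interface_structure):
        with pytest.warns(UserWarning):
            census = interface_census(interface_structure, "A", "B")
        assert census.n_hbond_pairs == 4
        assert census.n_hydrophobic_atom_contacts == 75
        assert census.n_hydrophobic_residue_pairs == 25
        assert census.n_salt_bridges == 0

    def test_rigid_transform_invariance(self, interface_structure):
        base = interface_census(interface_structure, "A", "B")
        rot = Rotation.random(random_state=7)
        moved = StructureModel(
            interface_structure.atoms,
            rot.apply(interface_structure.frames[0])[None] + np.array([13.0, -4.0, 8.0]))
        census = interface_census(moved, "A", "B")
        assert census.summary() == base.summary()

    def test_chain_swap_preserves_counts(self, interface_structure):
        a = interface_census(interface_structure, "A", "B")
        b = interface_census(interface_structure, "B", "A")
        assert a.summary() == b.summary()

    def test_cutoff_monotonicity(self, interface_structure):
        tight = ContactCriteria(hbond=HBondCriteria(donor_acceptor_cutoff=2.5),
                                hydrophobic=HydrophobicCriteria(cutoff=3.0))
        wide = ContactCriteria(hbond=HBondCriteria(donor_acceptor_cutoff=4.5),
                               hydrophobic=HydrophobicCriteria(cutoff=5.0))
        c_tight = interface_census(interface_structure, "A", "B", tight)
        c_wide = interface_census(interface_structure, "A", "B", wide)
        assert c_wide.n_hbond_pairs >= c_tight.n_hbond_pairs
        assert c_wide.n_hydrophobic_atom_contacts >= c_tight.n_hydrophobic_atom_contacts

    def test_hydrophobic_pairs_match_reference_table(self, interface_structure, reference_tables):
        _, t2 = reference_tables
        census = interface_census(interface_structure, "A", "B")
        detected = {frozenset((a.label, b.label))
                    for a, b in census.residue_pairs(ContactKind.HYDROPHOBIC)}
        expected = {frozenset(r.pair.split("-")) for r in t2}
        overlap = len(detected & expected) / len(expected)
        assert overlap >= 0.8
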