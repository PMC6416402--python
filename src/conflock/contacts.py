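"""Inter-chain contact classification: hydrogen bonds, hydrophobic contacts,
salt bridges.

The detectors reproduce a DIMPLOT-style interface census from geometry alone.
Crystal structures typically lack hydrogens, so hydrogen bonds default to
distance-only donor/acceptor criteria with donor/acceptor typing taken from a
built-in per-residue table; when explicit hydrogens are present the
donor-H...acceptor angle criterion is applied as well.

All cutoffs are configurable through the criteria dataclasses; the defaults
follow published LigPlot/HBPLUS conventions (donor-acceptor <= 3.35 A,
hydrophobic C/S atom pairs <= 3.90 A) and a 0.6 nm charged-group centroid
cutoff for salt bridges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .structure import AtomRecord, ResidueId, StructureModel, A_PER_NM

__all__ = [
    "ContactKind",
    "ContactRecord",
    "ContactCensus",
    "HBondCriteria",
    "HydrophobicCriteria",
    "SaltBridgeCriteria",
    "ContactCriteria",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_contacts",
    "detect_salt_bridges",
    "interface_census",
]


class ContactKind(str, Enum):
    HYDROGEN_BOND = "hydrogen_bond"
    HYDROPHOBIC = "hydrophobic"
    SALT_BRIDGE = "salt_bridge"


@dataclass(frozen=True)
class ContactRecord:
    """One classified inter-chain atom-level interaction."""

    residue_a: ResidueId
    residue_b: ResidueId
    kind: ContactKind
    atom_a: str
    atom_b: str
    distance: float  # Angstrom
    angle: float | None = None  # degrees, D-H...A when hydrogens present

    @property
    def pair_label(self) -> str:
        return f"{self.residue_a.label}-{self.residue_b.label}"


@dataclass
class ContactCensus:
    """Aggregated interface census over all three contact classes."""

    contacts: list[ContactRecord]
    n_hbond_pairs: int
    n_hydrophobic_atom_contacts: int
    n_hydrophobic_residue_pairs: int
    n_salt_bridges: int

    def residue_pairs(self, kind: ContactKind) -> list[tuple[ResidueId, ResidueId]]:
        seen: dict[tuple[ResidueId, ResidueId], None] = {}
        for c in self.contacts:
            if c.kind == kind:
                seen.setdefault((c.residue_a, c.residue_b), None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "residue_a": c.residue_a.label,
                    "residue_b": c.residue_b.label,
                    "kind": c.kind.value,
                    "atom_a": c.atom_a,
                    "atom_b": c.atom_b,
                    "distance_A": round(c.distance, 3),
                }
                for c in self.contacts
            ],
            columns=["residue_a", "residue_b", "kind", "atom_a", "atom_b", "distance_A"],
        )

    def summary(self) -> dict:
        return {
            "n_hbond_pairs": self.n_hbond_pairs,
            "n_hydrophobic_atom_contacts": self.n_hydrophobic_atom_contacts,
            "n_hydrophobic_residue_pairs": self.n_hydrophobic_residue_pairs,
            "n_salt_bridges": self.n_salt_bridges,
        }


@dataclass
class HBondCriteria:
    donor_acceptor_cutoff: float = 3.35   # A
    hydrogen_acceptor_cutoff: float = 2.70  # A, used only when H present
    min_dha_angle: float = 90.0           # degrees

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0 or self.hydrogen_acceptor_cutoff <= 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")


@dataclass
class HydrophobicCriteria:
    cutoff: float = 3.90  # A, apolar atom to apolar atom


@dataclass
class SaltBridgeCriteria:
    cutoff_nm: float = 0.6  # charged-group centroid separation

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("salt-bridge cutoff must be positive")


@dataclass
class ContactCriteria:
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    hydrophobic: HydrophobicCriteria = field(default_factory=HydrophobicCriteria)
    salt_bridge: SaltBridgeCriteria = field(default_factory=SaltBridgeCriteria)


# Donor/acceptor typing for distance-only hydrogen-bond detection on
# hydrogen-free crystal structures.  Backbone N donates, backbone O accepts,
# for every amino acid except proline's N.
_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"}, "TRP": {"NE1"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"OD1"}, "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}

_ANIONIC_GROUPS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}
_CATIONIC_GROUPS: dict[str, set[str]] = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}

# Carbons whose context is polar (bonded to O/N) are excluded from the
# hydrophobic class, LigPlot-style: the backbone carbonyl C plus side-chain
# carboxyl/amide/guanidinium carbons and hydroxyl-bearing carbons.
_POLAR_CARBONS: dict[str, set[str]] = {
    "*": {"C"},
    "ASP": {"CG"}, "GLU": {"CD"}, "ASN": {"CG"}, "GLN": {"CD"},
    "ARG": {"CZ"}, "SER": {"CB"}, "THR": {"CB"}, "TYR": {"CZ"},
    "LYS": {"CE"},
}


def _is_donor(atom: AtomRecord) -> bool:
    if atom.name == "N" and atom.residue_name != "PRO":
        return True
    return atom.name in _SIDECHAIN_DONORS.get(atom.residue_name, set())


def _is_acceptor(atom: AtomRecord) -> bool:
    if atom.name in ("O", "OXT"):
        return True
    return atom.name in _SIDECHAIN_ACCEPTORS.get(atom.residue_name, set())


def _is_apolar(atom: AtomRecord) -> bool:
    if atom.element.upper() not in ("C", "S"):
        return False
    if atom.name in _POLAR_CARBONS["*"]:
        return False
    return atom.name not in _POLAR_CARBONS.get(atom.residue_name, set())


def _chain_atoms(structure: StructureModel, chain: str, frame: int) -> tuple[list[AtomRecord], np.ndarray]:
    atoms = structure.chain_atoms(chain)  # excludes HETATM by default
    idx = structure.atom_indices(chain)
    return atoms, structure.frames[frame][idx]


def _ordered(res_a: ResidueId, res_b: ResidueId) -> tuple[ResidueId, ResidueId]:
    return (res_a, res_b)


def detect_hydrogen_bonds(structure: StructureModel, chain_a: str, chain_b: str,
                          criteria: HBondCriteria | None = None,
                          frame: int = 0) -> list[ContactRecord]:
    """Donor-acceptor N/O pairs across two chains within the distance cutoff.

    Both donor->acceptor directions are scanned; records carry the
    donor-acceptor distance.  With explicit hydrogens present on the donor
    residue, the best D-H...A angle must exceed ``min_dha_angle``.
    """
    crit = criteria or HBondCriteria()
    atoms_a, xyz_a = _chain_atoms(structure, chain_a, frame)
    atoms_b, xyz_b = _chain_atoms(structure, chain_b, frame)
    records: list[ContactRecord] = []
    for (donors, acceptors, d_xyz, a_xyz, swap) in (
        (atoms_a, atoms_b, xyz_a, xyz_b, False),
        (atoms_b, atoms_a, xyz_b, xyz_a, True),
    ):
        don_idx = [i for i, at in enumerate(donors) if _is_donor(at)]
        acc_idx = [j for j, at in enumerate(acceptors) if _is_acceptor(at)]
        if not don_idx or not acc_idx:
            continue
        dmat = np.linalg.norm(
            d_xyz[don_idx][:, None, :] - a_xyz[acc_idx][None, :, :], axis=-1)
        for ii, i in enumerate(don_idx):
            for jj, j in enumerate(acc_idx):
                dist = float(dmat[ii, jj])
                if dist > crit.donor_acceptor_cutoff or dist <= 0.0:
                    continue
                angle = _best_dha_angle(donors, d_xyz, i, a_xyz[acc_idx[jj]])
                if angle is not None and angle < crit.min_dha_angle:
                    continue
                don, acc = donors[i], acceptors[j]
                if swap:
                    rec = ContactRecord(acc.residue_id, don.residue_id,
                                        ContactKind.HYDROGEN_BOND,
                                        acc.name, don.name, dist, angle)
                else:
                    rec = ContactRecord(don.residue_id, acc.residue_id,
                                        ContactKind.HYDROGEN_BOND,
                                        don.name, acc.name, dist, angle)
                records.append(rec)
    return records


def _best_dha_angle(atoms: list[AtomRecord], xyz: np.ndarray, donor_i: int,
                    acceptor_xyz: np.ndarray) -> float | None:
    """Largest D-H...A angle over hydrogens bonded to the donor, or None."""
    donor = atoms[donor_i]
    hydrogens = [
        k for k, at in enumerate(atoms)
        if at.element.upper() in ("H", "D")
        and at.residue_seq == donor.residue_seq and at.chain_id == donor.chain_id
        and np.linalg.norm(xyz[k] - xyz[donor_i]) < 1.3
    ]
    if not hydrogens:
        return None
    best = 0.0
    for k in hydrogens:
        v1 = xyz[donor_i] - xyz[k]
        v2 = acceptor_xyz - xyz[k]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        best = max(best, float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
    return best


def detect_hydrophobic_contacts(structure: StructureModel, chain_a: str, chain_b: str,
                                criteria: HydrophobicCriteria | None = None,
                                frame: int = 0) -> list[ContactRecord]:
    """Apolar (C/S) atom pairs across the interface within the cutoff."""
    crit = criteria or HydrophobicCriteria()
    atoms_a, xyz_a = _chain_atoms(structure, chain_a, frame)
    atoms_b, xyz_b = _chain_atoms(structure, chain_b, frame)
    ai = [i for i, at in enumerate(atoms_a) if _is_apolar(at)]
    bi = [j for j, at in enumerate(atoms_b) if _is_apolar(at)]
    records: list[ContactRecord] = []
    if not ai or not bi:
        return records
    dmat = np.linalg.norm(xyz_a[ai][:, None, :] - xyz_b[bi][None, :, :], axis=-1)
    for ii, i in enumerate(ai):
        for jj, j in enumerate(bi):
            dist = float(dmat[ii, jj])
            if 0.0 < dist <= crit.cutoff:
                records.append(ContactRecord(
                    atoms_a[i].residue_id, atoms_b[j].residue_id,
                    ContactKind.HYDROPHOBIC, atoms_a[i].name, atoms_b[j].name, dist))
    return records


def detect_salt_bridges(structure: StructureModel, chain_a: str, chain_b: str,
                        criteria: SaltBridgeCriteria | None = None,
                        frame: int = 0) -> list[ContactRecord]:
    """Charged-group centroid contacts (Asp/Glu vs Lys/Arg/His) across chains."""
    crit = criteria or SaltBridgeCriteria()
    records: list[ContactRecord] = []
    for res_a, cen_a, sign_a in _charged_centroids(structure, chain_a, frame):
        for res_b, cen_b, sign_b in _charged_centroids(structure, chain_b, frame):
            if sign_a * sign_b >= 0:
                continue
            dist_nm = float(np.linalg.norm(cen_a - cen_b)) / A_PER_NM
            if dist_nm <= crit.cutoff_nm:
                records.append(ContactRecord(
                    res_a, res_b, ContactKind.SALT_BRIDGE,
                    "sidechain", "sidechain", dist_nm * A_PER_NM))
    return records


def _charged_centroids(structure: StructureModel, chain: str, frame: int):
    atoms, xyz = _chain_atoms(structure, chain, frame)
    by_res: dict[ResidueId, list[int]] = {}
    for i, at in enumerate(atoms):
        by_res.setdefault(at.residue_id, []).append(i)
    out = []
    for res, idx in by_res.items():
        for table, sign in ((_ANIONIC_GROUPS, -1), (_CATIONIC_GROUPS, +1)):
            names = table.get(res.residue_name)
            if not names:
                continue
            sel = [i for i in idx if atoms[i].name in names]
            if not sel:
                warnings.warn(f"{res.label}: charged side-chain atoms missing; "
                              "skipped for salt-bridge detection", stacklevel=2)
                continue
            out.append((res, xyz[sel].mean(axis=0), sign))
    return out


def interface_census(structure: StructureModel, chain_a: str, chain_b: str,
                     criteria: ContactCriteria | None = None,
                     frame: int = 0) -> ContactCensus:
    """Full interface census across two chains.

    ``n_hbond_pairs`` counts unique residue pairs (not atom pairs);
    hydrophobic contacts are reported both per atom pair and collapsed to
    unordered residue pairs.
    """
    crit = criteria or ContactCriteria()
    hb = detect_hydrogen_bonds(structure, chain_a, chain_b, crit.hbond, frame)
    ph = detect_hydrophobic_contacts(structure, chain_a, chain_b, crit.hydrophobic, frame)
    sb = detect_salt_bridges(structure, chain_a, chain_b, crit.salt_bridge, frame)
    contacts = hb + ph + sb
    hb_pairs = {(c.residue_a, c.residue_b) for c in hb}
    ph_pairs = {frozenset((c.residue_a, c.residue_b)) for c in ph}
    return ContactCensus(
        contacts=contacts,
        n_hbond_pairs=len(hb_pairs),
        n_hydrophobic_atom_contacts=len(ph),
        n_hydrophobic_residue_pairs=len(ph_pairs),
        n_salt_bridges=len(sb),
    )
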