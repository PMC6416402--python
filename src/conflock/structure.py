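"""Minimal macromolecular structure model with PDB I/O and geometry primitives.

Coordinates are stored in Angstrom internally (the PDB native unit); every
distance returned by the public geometry API (:func:`center_of_mass`,
:func:`com_distance`, :func:`rmsd`) is in nanometres, the unit convention of
MD packages and of the analyses this library supports.

Multi-model PDB files are accepted and exposed as a small trajectory: each
``MODEL``/``ENDMDL`` block becomes one coordinate frame with identical atom
ordering.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from functools import total_ordering
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "ResidueId",
    "StructureModel",
    "PDBParseError",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "center_of_mass",
    "com_distance",
    "rmsd",
]

A_PER_NM = 10.0

# Standard atomic weights (Da), 2021 IUPAC abridged values; enough coverage
# for protein structures plus the common hetero metals/halides.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45,
    "BR": 79.904, "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "FE": 55.845, "CO": 58.933, "NI": 58.693,
    "CU": 63.546, "ZN": 65.38, "CD": 112.414, "HG": 200.592,
}


class PDBParseError(ValueError):
    """A fixed-column record could not be parsed; the message names the line."""


class EmptyStructureError(ValueError):
    """The file contained no ATOM records."""


@dataclass(frozen=True)
@total_ordering
class ResidueId:
    """Identity of one residue, ordered by (chain, sequence number).

    The canonical display ``label`` follows the residue-pair naming used for
    interface tables, e.g. ``Ile149A`` = residue name + sequence + chain.
    """

    chain_id: str
    residue_seq: int
    residue_name: str

    @property
    def label(self) -> str:
        return f"{self.residue_name.capitalize()}{self.residue_seq}{self.chain_id}"

    @classmethod
    def from_label(cls, label: str) -> "ResidueId":
        m = re.fullmatch(r"([A-Za-z]{1,3})(\d+)([A-Za-z0-9])", label.strip())
        if m is None:
            raise ValueError(f"cannot parse residue label {label!r}")
        name, seq, chain = m.groups()
        return cls(chain_id=chain, residue_seq=int(seq), residue_name=name.upper())

    def _key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)

    def __lt__(self, other: "ResidueId") -> bool:
        return self._key() < other._key()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass
class AtomRecord:
    """One ATOM/HETATM record; coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: np.ndarray
    mass: float
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetatm: bool = False
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")
        if not self.chain_id:
            raise ValueError(f"atom {self.serial}: chain_id must be non-empty")

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.residue_seq, self.residue_name)


def element_mass(element: str, atom_name: str = "") -> float:
    """Mass for an element symbol; unknown elements fall back to carbon."""
    el = element.strip().upper()
    if not el and atom_name:
        el = _guess_element(atom_name)
    if el in ATOMIC_MASSES:
        return ATOMIC_MASSES[el]
    warnings.warn(f"unknown element {element!r}; using carbon mass", stacklevel=2)
    return ATOMIC_MASSES["C"]


def _guess_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (e.g. 'CA' -> C, 'OD1' -> O)."""
    name = atom_name.strip()
    if not name:
        return ""
    # Two-letter metals are left-justified into column 13 in real files;
    # after stripping we check the two-letter symbol first.
    if name[:2].upper() in ATOMIC_MASSES and name[:2].upper() not in ("CA", "CD", "CO", "NA"):
        return name[:2].upper()
    first = name.lstrip("0123456789")[:1].upper()
    return first


class StructureModel:
    """An ordered atom list plus one or more coordinate frames.

    ``atoms`` holds the per-atom metadata (with frame-0 coordinates);
    ``frames`` is an (M, N, 3) array in Angstrom with identical atom ordering
    in every frame.
    """

    def __init__(self, atoms: Sequence[AtomRecord], frames: np.ndarray | None = None,
                 pdb_id: str = ""):
        self.atoms: list[AtomRecord] = list(atoms)
        if not self.atoms:
            raise EmptyStructureError("structure has no atoms")
        if frames is None:
            frames = np.asarray([a.coords for a in self.atoms], dtype=float)[None, :, :]
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1] != len(self.atoms) or frames.shape[2] != 3:
            raise ValueError("frames must have shape (M, n_atoms, 3)")
        self.frames = frames
        self.pdb_id = pdb_id

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def chain_ids(self) -> list[str]:
        """Chain identifiers in first-appearance order (deterministic)."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def atom_indices(self, chain_id: str | None = None,
                     predicate: Callable[[AtomRecord], bool] | None = None,
                     include_hetatm: bool = False) -> np.ndarray:
        idx = []
        for i, a in enumerate(self.atoms):
            if a.is_hetatm and not include_hetatm:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if predicate is not None and not predicate(a):
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def chain_atoms(self, chain_id: str, include_hetatm: bool = False) -> list[AtomRecord]:
        if chain_id not in self.chain_ids():
            raise KeyError(f"chain {chain_id!r} not in structure "
                           f"(has {self.chain_ids()})")
        return [self.atoms[i] for i in self.atom_indices(chain_id, include_hetatm=include_hetatm)]

    def residues(self, chain_id: str | None = None) -> list[ResidueId]:
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            if a.is_hetatm:
                continue
            if chain_id is None or a.chain_id == chain_id:
                seen.setdefault(a.residue_id, None)
        return list(seen)

    def coords(self, frame: int = 0) -> np.ndarray:
        return self.frames[frame]


_ATOM_RE = ("ATOM", "HETATM")


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed {line[:6].strip()} record at line {lineno}: {exc}") from exc
    if not element:
        element = _guess_element(name)
    return AtomRecord(
        serial=serial, name=name, element=element, residue_name=res_name,
        chain_id=chain_id, residue_seq=res_seq, coords=np.array([x, y, z]),
        mass=element_mass(element, name), occupancy=occ, b_factor=bfac,
        is_hetatm=line.startswith("HETATM"), altloc=altloc,
    )


def read_pdb(path: str | Path) -> StructureModel:
    """Parse a (possibly multi-model) PDB file.

    HETATM records (waters, ions, metal cofactors) are retained but flagged
    ``is_hetatm`` and excluded from interface analysis by default.  Alternate
    locations keep the highest-occupancy conformer (first encountered on tie).
    """
    path = Path(path)
    pdb_id = ""
    model_atoms: list[list[AtomRecord]] = [[]]
    in_model = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "HEADER":
                pdb_id = line[62:66].strip() if len(line) >= 66 else ""
            elif rec == "MODEL":
                if in_model or model_atoms[-1]:
                    model_atoms.append([])
                in_model = True
            elif rec == "ENDMDL":
                in_model = False
            elif rec in _ATOM_RE:
                model_atoms[-1].append(_parse_atom_line(line.rstrip("\n"), lineno))
    model_atoms = [m for m in model_atoms if m]
    if not model_atoms or not any(not a.is_hetatm for a in model_atoms[0]):
        raise EmptyStructureError(f"{path}: no ATOM records found")

    keep = _resolve_altlocs(model_atoms[0])
    atoms = [model_atoms[0][i] for i in keep]
    frames = [np.asarray([a.coords for a in atoms])]
    key0 = [(a.serial, a.name, a.altloc) for a in atoms]
    for m, frame_atoms in enumerate(model_atoms[1:], start=2):
        sel = _resolve_altlocs(frame_atoms)
        frame = [frame_atoms[i] for i in sel]
        if [(a.serial, a.name, a.altloc) for a in frame] != key0:
            raise PDBParseError(
                f"{path}: MODEL {m} atom list differs from MODEL 1")
        frames.append(np.asarray([a.coords for a in frame]))
    return StructureModel(atoms, np.stack(frames), pdb_id=pdb_id)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[int]:
    """Indices keeping one conformer per atom: highest occupancy, tie -> first."""
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.residue_seq, a.residue_name, a.name, a.is_hetatm)
        if key not in best:
            best[key] = i
            order.append(key)
        elif atoms[i].occupancy > atoms[best[key]].occupancy:
            best[key] = i
    return sorted(best[k] for k in order)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write all frames as fixed-column PDB (MODEL blocks when multi-frame)."""
    path = Path(path)
    multi = structure.n_frames > 1
    with path.open("w") as fh:
        if structure.pdb_id:
            fh.write(f"HEADER{'':56s}{structure.pdb_id:>4s}\n")
        for m in range(structure.n_frames):
            if multi:
                fh.write(f"MODEL     {m + 1:4d}\n")
            prev_chain = None
            for a, xyz in zip(structure.atoms, structure.frames[m]):
                if prev_chain is not None and a.chain_id != prev_chain and not a.is_hetatm:
                    fh.write("TER\n")
                prev_chain = a.chain_id
                rec = "HETATM" if a.is_hetatm else "ATOM  "
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"{rec}{a.serial:5d} {name}{a.altloc or ' ':1s}{a.residue_name:>3s} "
                    f"{a.chain_id:1s}{a.residue_seq:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.b_factor:6.2f}{'':10s}{a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def center_of_mass(structure: StructureModel, chain_id: str, frame: int = 0,
                   include_hetatm: bool = False) -> np.ndarray:
    """Mass-weighted mean position of a chain, in nm."""
    idx = structure.atom_indices(chain_id, include_hetatm=include_hetatm)
    if idx.size == 0:
        raise KeyError(f"chain {chain_id!r} not in structure "
                       f"(has {structure.chain_ids()})")
    masses = np.asarray([structure.atoms[i].mass for i in idx])
    xyz = structure.frames[frame][idx]
    return (masses[:, None] * xyz).sum(axis=0) / masses.sum() / A_PER_NM


def com_distance(structure: StructureModel, chain_a: str, chain_b: str,
                 frame: int = 0) -> float:
    """Distance between two chain centres of mass, in nm."""
    ca = center_of_mass(structure, chain_a, frame)
    cb = center_of_mass(structure, chain_b, frame)
    return float(np.linalg.norm(ca - cb))


def rmsd(structure: StructureModel, frame: int, reference_frame: int = 0,
         selection: Callable[[AtomRecord], bool] | None = None,
         fit: bool = True) -> float:
    """RMSD (nm) of one frame against a reference frame.

    When ``fit`` is true the mobile frame is optimally superposed on the
    reference (Kabsch least-squares rotation after centroid removal) before
    the deviation is computed.  Default selection: Calpha atoms.
    """
    if selection is None:
        selection = lambda a: a.name == "CA" and not a.is_hetatm
    idx = structure.atom_indices(predicate=selection)
    if idx.size == 0:
        raise ValueError("selection matched no atoms")
    ref = structure.frames[reference_frame][idx]
    mob = structure.frames[frame][idx]
    return rmsd_coords(ref, mob, fit=fit) / A_PER_NM


def rmsd_coords(ref: np.ndarray, mob: np.ndarray, fit: bool = True) -> float:
    """RMSD between two (N, 3) coordinate sets, in the input unit."""
    ref = np.asarray(ref, dtype=float)
    mob = np.asarray(mob, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ: {ref.shape} vs {mob.shape}")
    if fit:
        if ref.shape[0] < 3 or _is_degenerate(ref) or _is_degenerate(mob):
            warnings.warn("degenerate selection for superposition; "
                          "falling back to unfitted RMSD", stacklevel=2)
        else:
            refc = ref - ref.mean(axis=0)
            mobc = mob - mob.mean(axis=0)
            rot, _ = Rotation.align_vectors(refc, mobc)
            mob = rot.apply(mobc) + ref.mean(axis=0)
            ref = refc + ref.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((ref - mob) ** 2, axis=1))))


def _is_degenerate(xyz: np.ndarray) -> bool:
    c = xyz - xyz.mean(axis=0)
    return np.linalg.matrix_rank(c, tol=1e-8) < 2
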