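"""All-atom peptide structures and PDB file I/O.

The in-memory container is :class:`HelixStructure`: an ordered list of
residues, each holding its heavy atoms as :class:`AtomRecord` objects.
Residue indices are 1-based everywhere a user sees them; internal arrays are
0-based. PDB parsing and writing go through gemmi; hydrogens are dropped on
read and never written, alternate conformations are resolved to the
highest-occupancy conformer (ties broken by altloc letter).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .geomtable import AA3_TO_1, heavy_atom_names
from .geometry import dihedral

__all__ = ["AtomRecord", "Residue", "HelixStructure", "PDBError", "read_pdb", "write_pdb"]

BACKBONE = ("N", "CA", "C", "O")


class PDBError(ValueError):
    """Structured error for unreadable or chemically incomplete PDB content."""


@dataclass
class AtomRecord:
    atom_name: str
    residue_index: int  # 1-based ordinal within the chain
    residue_type: str   # 3-letter code
    position: np.ndarray  # (3,) Angstrom

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_name}: position must be a finite 3-vector")
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")


@dataclass
class Residue:
    residue_type: str
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        raise KeyError(name)

    def has(self, name: str) -> bool:
        return any(a.atom_name == name for a in self.atoms)

    def pos(self, name: str) -> np.ndarray:
        return self.atom(name).position


@dataclass
class HelixStructure:
    """All-atom peptide chain: residue identities, coordinates, chirality."""

    residues: list[Residue]
    chirality: str = "L"  # "L" or "D"; geometric annotation, not a format flag

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(r.residue_type, "X") for r in self.residues)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array over all atoms in chain order."""
        return np.array([a.position for r in self.residues for a in r.atoms])

    def with_coords(self, xyz: np.ndarray) -> "HelixStructure":
        """Copy of the structure with coordinates replaced (chain order)."""
        xyz = np.asarray(xyz, dtype=float)
        out, k = [], 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(replace(a, position=xyz[k].copy()))
                k += 1
            out.append(Residue(r.residue_type, atoms))
        if k != len(xyz):
            raise ValueError("coordinate count mismatch")
        return HelixStructure(out, chirality=self.chirality)

    def validate(self, min_length: int = 1) -> None:
        if self.length < min_length:
            raise ValueError(f"structure has {self.length} residues; need >= {min_length}")
        for i, r in enumerate(self.residues, start=1):
            for name in BACKBONE:
                if not r.has(name):
                    raise PDBError(f"residue {i} ({r.residue_type}): missing backbone atom {name}")
        cas = np.array([r.pos("CA") for r in self.residues])
        d = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        if len(d) and (d.min() <= 2.5 or d.max() >= 4.5):
            bad = int(np.argmax((d <= 2.5) | (d >= 4.5))) + 1
            raise PDBError(
                f"consecutive CA-CA distance {d[bad - 1]:.2f} A between residues "
                f"{bad} and {bad + 1} outside (2.5, 4.5)"
            )


def _infer_chirality(residues: list[Residue]) -> str:
    """Majority sign of the N-CA-C-CB improper (+~120 deg for L residues)."""
    votes = []
    for r in residues:
        if r.has("CB"):
            try:
                votes.append(dihedral(r.pos("N"), r.pos("CA"), r.pos("C"), r.pos("CB")))
            except (KeyError, ValueError):
                continue
    if not votes:
        return "L"
    return "L" if float(np.median(votes)) > 0 else "D"


def read_pdb(path: str | Path) -> HelixStructure:
    """Read the first chain of a PDB file into a :class:`HelixStructure`.

    HETATM records, waters and hydrogens are ignored; alternate locations are
    resolved to the highest-occupancy conformer (ties: lowest altloc letter).
    Every residue must carry the four backbone heavy atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBError(f"unparseable PDB file {path.name}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0 or len(st[0]) == 0:
        raise PDBError(f"{path.name}: no chains with ATOM records")
    chain = st[0][0]
    residues: list[Residue] = []
    for i, res in enumerate(chain, start=1):
        if res.het_flag != "A":
            continue
        picked: dict[str, gemmi.Atom] = {}
        for atom in res:
            if atom.is_hydrogen():
                continue
            prev = picked.get(atom.name)
            if (
                prev is None
                or atom.occ > prev.occ
                or (atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~"))
            ):
                picked[atom.name] = atom
        atoms = [
            AtomRecord(a.name, i, res.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
            for a in picked.values()
        ]
        # keep the canonical atom order where known, extras after
        order = {n: k for k, n in enumerate(heavy_atom_names(res.name))} if res.name in AA3_TO_1 else {}
        atoms.sort(key=lambda a: order.get(a.atom_name, len(order) + 1))
        residues.append(Residue(res.name, atoms))
    if not residues:
        raise PDBError(f"{path.name}: no amino-acid ATOM records in first chain")
    struct = HelixStructure(residues, chirality=_infer_chirality(residues))
    struct.validate()
    return struct


def write_pdb(structure: HelixStructure, path: str | Path) -> None:
    """Write fixed-column ATOM records (3-decimal coordinates, element column,
    TER at chain end). D-chirality structures keep standard residue names and
    get a REMARK line declaring the chirality."""
    if structure.length == 0:
        raise ValueError("cannot write an empty structure")
    st = gemmi.Structure()
    st.name = "helixsde"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, r in enumerate(structure.residues, start=1):
        res = gemmi.Residue()
        res.name = r.residue_type
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "A"
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.pos = gemmi.Position(*a.position)
            atom.occ = 1.0
            atom.b_iso = 0.0
            atom.element = gemmi.Element(_element_of(a.atom_name))
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    if structure.chirality == "D":
        st.raw_remarks = ["REMARK 999 ALL RESIDUES ARE D-AMINO ACIDS (MIRROR-IMAGE PEPTIDE)"]
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


def _element_of(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"
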