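"""Idealized covalent geometry used for internal-coordinate reconstruction.

Only angles are encoded in the diffusion feature map; every bond length and
every angle that is not one of the ten encoded channels comes from this table.
Side chains are described as NeRF templates: each heavy atom is placed from
three previously placed atoms with an ideal bond length, an ideal bond angle
and a torsion that is either one of the residue's chi angles (plus a fixed
branch offset) or a fixed value (planar groups).

Prochiral branch offsets (CB placement, e.g. VAL CG2, ring +-120 positions)
are stored with their L-amino-acid sign; a decoder building a D residue must
negate them (the encoded channels themselves carry the mirror information for
everything else).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

# canonical 20 residues, alphabetical by 3-letter code; this is also the
# column order of the one-hot sequence block and the argmax tie-break order
AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA3_TO_INDEX = {aa: i for i, aa in enumerate(AA3)}
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# backbone bond lengths, Angstrom
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530

# ideal backbone bond angles, degrees (used by the ideal-helix builder and
# as the synthetic generator's default means)
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.6

# CB torsion: dihedral N-C-CA-CB for an L amino acid. The sign makes the
# improper N-CA-C-CB come out near +34 deg (the L convention); D flips it.
TORSION_N_C_CA_CB = -122.6

# torsion spec: ("chi", k, offset_deg) with k in 1..4, or ("fix", deg)
Torsion = tuple[Literal["chi", "fix"], float, float]


@dataclass(frozen=True)
class AtomTemplate:
    name: str
    refs: tuple[str, str, str]  # (a, b, parent); torsion is a-b-parent-atom
    length: float               # bond length parent-atom, Angstrom
    angle: float                # bond angle b-parent-atom, degrees
    torsion: Torsion


def _t(name, refs, length, angle, kind, k_or_deg, offset=0.0) -> AtomTemplate:
    if kind == "chi":
        return AtomTemplate(name, refs, length, angle, ("chi", float(k_or_deg), float(offset)))
    return AtomTemplate(name, refs, length, angle, ("fix", float(k_or_deg), 0.0))


# Heavy side-chain atoms beyond CB. Geometry from standard idealized values;
# ring closure is not enforced (planar groups are generated planar by
# construction, proline is built as an open chain from chi1/chi2).
SIDECHAINS: dict[str, tuple[AtomTemplate, ...]] = {
    "ALA": (),
    "GLY": (),
    "SER": (_t("OG", ("N", "CA", "CB"), 1.417, 110.8, "chi", 1),),
    "CYS": (_t("SG", ("N", "CA", "CB"), 1.808, 114.0, "chi", 1),),
    "THR": (
        _t("OG1", ("N", "CA", "CB"), 1.433, 109.6, "chi", 1),
        _t("CG2", ("N", "CA", "CB"), 1.521, 110.5, "chi", 1, -120.0),
    ),
    "VAL": (
        _t("CG1", ("N", "CA", "CB"), 1.527, 110.5, "chi", 1),
        _t("CG2", ("N", "CA", "CB"), 1.527, 110.5, "chi", 1, 120.0),
    ),
    "LEU": (
        _t("CG", ("N", "CA", "CB"), 1.530, 116.3, "chi", 1),
        _t("CD1", ("CA", "CB", "CG"), 1.524, 110.7, "chi", 2),
        _t("CD2", ("CA", "CB", "CG"), 1.524, 110.7, "chi", 2, 120.0),
    ),
    "ILE": (
        _t("CG1", ("N", "CA", "CB"), 1.530, 110.4, "chi", 1),
        _t("CG2", ("N", "CA", "CB"), 1.521, 110.5, "chi", 1, -120.0),
        _t("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, "chi", 2),
    ),
    "MET": (
        _t("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi", 1),
        _t("SD", ("CA", "CB", "CG"), 1.803, 112.7, "chi", 2),
        _t("CE", ("CB", "CG", "SD"), 1.791, 100.9, "chi", 3),
    ),
    "PRO": (
        _t("CG", ("N", "CA", "CB"), 1.495, 104.5, "chi", 1),
        _t("CD", ("CA", "CB", "CG"), 1.503, 106.1, "chi", 2),
    ),
    "PHE": (
        _t("CG", ("N", "CA", "CB"), 1.502, 113.8, "chi", 1),
        _t("CD1", ("CA", "CB", "CG"), 1.390, 120.8, "chi", 2),
        _t("CD2", ("CA", "CB", "CG"), 1.390, 120.8, "chi", 2, 180.0),
        _t("CE1", ("CB", "CG", "CD1"), 1.390, 120.8, "fix", 180.0),
        _t("CE2", ("CB", "CG", "CD2"), 1.390, 120.8, "fix", 180.0),
        _t("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, "fix", 0.0),
    ),
    "TYR": (
        _t("CG", ("N", "CA", "CB"), 1.502, 113.8, "chi", 1),
        _t("CD1", ("CA", "CB", "CG"), 1.390, 120.8, "chi", 2),
        _t("CD2", ("CA", "CB", "CG"), 1.390, 120.8, "chi", 2, 180.0),
        _t("CE1", ("CB", "CG", "CD1"), 1.390, 120.8, "fix", 180.0),
        _t("CE2", ("CB", "CG", "CD2"), 1.390, 120.8, "fix", 180.0),
        _t("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, "fix", 0.0),
        _t("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, "fix", 180.0),
    ),
    "TRP": (
        _t("CG", ("N", "CA", "CB"), 1.498, 113.6, "chi", 1),
        _t("CD1", ("CA", "CB", "CG"), 1.365, 126.9, "chi", 2),
        _t("CD2", ("CA", "CB", "CG"), 1.433, 126.7, "chi", 2, 180.0),
        _t("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, "fix", 180.0),
        _t("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, "fix", 180.0),
        _t("CE3", ("CD1", "CG", "CD2"), 1.398, 133.9, "fix", 180.0),
        _t("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, "fix", 180.0),
        _t("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, "fix", 180.0),
        _t("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, "fix", 0.0),
    ),
    "HIS": (
        _t("CG", ("N", "CA", "CB"), 1.497, 113.8, "chi", 1),
        _t("ND1", ("CA", "CB", "CG"), 1.371, 122.7, "chi", 2),
        _t("CD2", ("CA", "CB", "CG"), 1.356, 131.1, "chi", 2, 180.0),
        _t("CE1", ("CB", "CG", "ND1"), 1.319, 109.0, "fix", 180.0),
        _t("NE2", ("CG", "ND1", "CE1"), 1.374, 111.7, "fix", 0.0),
    ),
    "ASP": (
        _t("CG", ("N", "CA", "CB"), 1.516, 113.0, "chi", 1),
        _t("OD1", ("CA", "CB", "CG"), 1.249, 118.5, "chi", 2),
        _t("OD2", ("CA", "CB", "CG"), 1.249, 118.5, "chi", 2, 180.0),
    ),
    "ASN": (
        _t("CG", ("N", "CA", "CB"), 1.516, 112.7, "chi", 1),
        _t("OD1", ("CA", "CB", "CG"), 1.231, 120.8, "chi", 2),
        _t("ND2", ("CA", "CB", "CG"), 1.328, 116.4, "chi", 2, 180.0),
    ),
    "GLU": (
        _t("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi", 1),
        _t("CD", ("CA", "CB", "CG"), 1.516, 112.6, "chi", 2),
        _t("OE1", ("CB", "CG", "CD"), 1.249, 118.5, "chi", 3),
        _t("OE2", ("CB", "CG", "CD"), 1.249, 118.5, "chi", 3, 180.0),
    ),
    "GLN": (
        _t("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi", 1),
        _t("CD", ("CA", "CB", "CG"), 1.516, 112.6, "chi", 2),
        _t("OE1", ("CB", "CG", "CD"), 1.231, 120.8, "chi", 3),
        _t("NE2", ("CB", "CG", "CD"), 1.328, 116.4, "chi", 3, 180.0),
    ),
    "LYS": (
        _t("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi", 1),
        _t("CD", ("CA", "CB", "CG"), 1.520, 111.3, "chi", 2),
        _t("CE", ("CB", "CG", "CD"), 1.520, 111.3, "chi", 3),
        _t("NZ", ("CG", "CD", "CE"), 1.489, 111.9, "chi", 4),
    ),
    "ARG": (
        _t("CG", ("N", "CA", "CB"), 1.520, 114.1, "chi", 1),
        _t("CD", ("CA", "CB", "CG"), 1.520, 111.3, "chi", 2),
        _t("NE", ("CB", "CG", "CD"), 1.461, 112.0, "chi", 3),
        _t("CZ", ("CG", "CD", "NE"), 1.329, 124.2, "chi", 4),
        _t("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, "fix", 0.0),
        _t("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, "fix", 180.0),
    ),
}


def n_chi(residue_type: str) -> int:
    """Number of chi torsion channels used by a residue type (0..4)."""
    if residue_type not in SIDECHAINS:
        raise KeyError(f"unknown residue type: {residue_type!r}")
    ks = [int(t.torsion[1]) for t in SIDECHAINS[residue_type] if t.torsion[0] == "chi"]
    return max(ks) if ks else 0


def chi_atom_names(residue_type: str) -> list[tuple[str, str, str, str]]:
    """The 4-atom quadruples defining chi_1..chi_n for a residue type.

    By construction the quadruple for chi_k is (a, b, parent, atom) of the
    template atom placed with torsion ("chi", k, 0).
    """
    quads: dict[int, tuple[str, str, str, str]] = {}
    for t in SIDECHAINS[residue_type]:
        kind, k, off = t.torsion
        if kind == "chi" and off == 0.0 and int(k) not in quads:
            quads[int(k)] = (*t.refs, t.name)
    return [quads[k] for k in sorted(quads)]


def sidechain_atom_names(residue_type: str) -> list[str]:
    names = [] if residue_type == "GLY" else ["CB"]
    names += [t.name for t in SIDECHAINS[residue_type]]
    return names


def heavy_atom_names(residue_type: str) -> list[str]:
    """Backbone + side-chain heavy atom names in this package's fixed order."""
    return ["N", "CA", "C", "O"] + sidechain_atom_names(residue_type)


def deg2rad(x):
    return np.deg2rad(x)
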