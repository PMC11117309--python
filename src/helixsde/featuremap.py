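"""The image-like helix representation: one-hot sequence block plus
normalized internal-coordinate angle channels, and the exact inverse
reconstruction to all-atom Cartesian coordinates.

A peptide of length L is encoded as an L x (20 + 10) matrix. The 20 sequence
columns are one-hot amino-acid scores; the 10 angle channels are, in order,

    phi, psi, omega,                     backbone torsions
    tau(N-CA-C), tau(CA-C-N+1), tau(C-1-N-CA),   backbone bond angles
    chi1..chi4                           side-chain torsions

each stored as angle_radians / pi, so torsions live in (-1, 1] and bond
angles in [0, 1]. Channels that are undefined for a residue (phi of residue
1, psi/omega of the last residue, chi slots a residue type does not have)
hold the mask value 0 and are flagged False in the validity mask.

Bond lengths are never encoded: decoding rebuilds the chain by sequential
natural-extension placement using ideal lengths from :mod:`helixsde.geomtable`,
starting from a canonical frame (N1 at the origin, CA1 on +x, C1 in the
xy-plane). Feature maps therefore carry no global pose.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geomtable as gt
from .geometry import bond_angle, dihedral, place_atom
from .pdb_io import AtomRecord, HelixStructure, Residue

__all__ = [
    "ANGLE_CHANNELS",
    "N_ANGLE_CHANNELS",
    "N_FEATURES",
    "HelixFeatureMap",
    "encode",
    "decode",
    "build_ideal_helix",
    "save_maps_npz",
    "load_maps_npz",
]

ANGLE_CHANNELS = (
    "phi", "psi", "omega",
    "tau_n_ca_c", "tau_ca_c_n", "tau_c_n_ca",
    "chi1", "chi2", "chi3", "chi4",
)
N_ANGLE_CHANNELS = len(ANGLE_CHANNELS)
N_FEATURES = 20 + N_ANGLE_CHANNELS

# default chi rotamer modes per residue type, degrees, one tuple per chi slot;
# the first mode of each slot is the "ideal" value used by build_ideal_helix
CHI_MODES: dict[str, tuple[tuple[float, ...], ...]] = {
    "ALA": (), "GLY": (),
    "SER": ((-60.0, 180.0, 60.0),),
    "CYS": ((-60.0, 180.0, 60.0),),
    "THR": ((-60.0, 180.0, 60.0),),
    "VAL": ((180.0, -60.0, 60.0),),
    "LEU": ((-60.0, 180.0), (180.0, 60.0)),
    "ILE": ((-60.0, 180.0, 60.0), (170.0, 60.0)),
    "MET": ((-60.0, 180.0, 60.0), (180.0, 60.0, -60.0), (180.0, 75.0, -75.0)),
    "PRO": ((25.0, -25.0), (-35.0, 35.0)),
    "PHE": ((-60.0, 180.0), (90.0, -90.0)),
    "TYR": ((-60.0, 180.0), (90.0, -90.0)),
    "TRP": ((-60.0, 180.0), (90.0, -90.0)),
    "HIS": ((-60.0, 180.0), (90.0, -90.0)),
    "ASP": ((-60.0, 180.0), (-30.0, 30.0, 90.0)),
    "ASN": ((-60.0, 180.0), (-30.0, 30.0, 90.0)),
    "GLU": ((-60.0, 180.0, 60.0), (180.0, 60.0, -60.0), (-30.0, 30.0, 90.0)),
    "GLN": ((-60.0, 180.0, 60.0), (180.0, 60.0, -60.0), (-30.0, 30.0, 90.0)),
    "LYS": ((-60.0, 180.0, 60.0),) * 4,
    "ARG": ((-60.0, 180.0, 60.0),) * 4,
}

IDEAL_PHI = -57.0
IDEAL_PSI = -47.0
IDEAL_OMEGA = 180.0


@dataclass
class HelixFeatureMap:
    """One-hot sequence block + normalized angle channels + validity mask."""

    seq: np.ndarray            # (L, 20) scores in [0, 1]
    ang: np.ndarray            # (L, 10) angles / pi
    valid: np.ndarray = field(default=None)  # (L, 10) bool, False = padded/undefined

    def __post_init__(self):
        self.seq = np.asarray(self.seq, dtype=float)
        self.ang = np.asarray(self.ang, dtype=float)
        if self.seq.ndim != 2 or self.seq.shape[1] != 20:
            raise ValueError("seq block must be (L, 20)")
        if self.ang.shape != (self.seq.shape[0], N_ANGLE_CHANNELS):
            raise ValueError("angle block must be (L, 10)")
        if self.valid is None:
            self.valid = np.ones_like(self.ang, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def length(self) -> int:
        return self.seq.shape[0]

    def array(self) -> np.ndarray:
        """(L, 30) concatenation [seq | angles] — the tensor the SDE diffuses."""
        return np.concatenate([self.seq, self.ang], axis=1)

    @classmethod
    def from_array(cls, x: np.ndarray, valid: np.ndarray | None = None) -> "HelixFeatureMap":
        x = np.asarray(x, dtype=float)
        return cls(x[:, :20], x[:, 20:], valid)

    @property
    def sequence(self) -> str:
        """Per-row argmax sequence (ties -> lowest index in AA3 order)."""
        return "".join(gt.AA3_TO_1[gt.AA3[i]] for i in np.argmax(self.seq, axis=1))

    def to_csv(self, path: str | Path) -> None:
        cols = list(gt.AA3) + [f"ang_{c}" for c in ANGLE_CHANNELS] + [f"valid_{c}" for c in ANGLE_CHANNELS]
        df = pd.DataFrame(
            np.concatenate([self.seq, self.ang, self.valid.astype(float)], axis=1),
            columns=cols,
        )
        df.index = np.arange(1, self.length + 1)
        df.index.name = "residue"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "HelixFeatureMap":
        df = pd.read_csv(path, index_col=0)
        seq = df[list(gt.AA3)].to_numpy()
        ang = df[[f"ang_{c}" for c in ANGLE_CHANNELS]].to_numpy()
        valid = df[[f"valid_{c}" for c in ANGLE_CHANNELS]].to_numpy() > 0.5
        return cls(seq, ang, valid)


def standard_valid_mask(sequence: str) -> np.ndarray:
    """The (L, 10) validity mask implied by a sequence: terminal phi/psi/
    omega and inter-residue bond angles masked, chi slots per residue type."""
    L = len(sequence)
    valid = np.zeros((L, N_ANGLE_CHANNELS), dtype=bool)
    valid[:, 3] = True
    valid[1:, 0] = valid[1:, 5] = True
    valid[:-1, 1] = valid[:-1, 2] = valid[:-1, 4] = True
    for i, aa in enumerate(sequence):
        rtype = gt.AA1_TO_3[aa.upper()]
        valid[i, 6:6 + gt.n_chi(rtype)] = True
    return valid


def save_maps_npz(maps: list[HelixFeatureMap], path: str | Path) -> None:
    """Batch container for training sets (documented: arrays x (N,L,30) and
    valid (N,L,10) in a compressed npz)."""
    x = np.stack([m.array() for m in maps])
    valid = np.stack([m.valid for m in maps])
    np.savez_compressed(path, x=x, valid=valid)


def load_maps_npz(path: str | Path) -> list[HelixFeatureMap]:
    data = np.load(path)
    return [HelixFeatureMap.from_array(xi, vi) for xi, vi in zip(data["x"], data["valid"])]


def _wrap(v: np.ndarray) -> np.ndarray:
    """Wrap normalized angles into (-1, 1] (period 2, i.e. angle period 2*pi)."""
    w = np.mod(np.asarray(v, dtype=float) + 1.0, 2.0) - 1.0
    return np.where(w == -1.0, 1.0, w)


def encode(structure: HelixStructure) -> HelixFeatureMap:
    """Encode an all-atom structure into its feature map.

    Angles are measured with :func:`helixsde.geometry.dihedral` /
    :func:`~helixsde.geometry.bond_angle`; undefined channels get the mask
    value 0 and ``valid=False``.
    """
    L = structure.length
    for i, r in enumerate(structure.residues, start=1):
        if r.residue_type not in gt.AA3_TO_INDEX:
            raise ValueError(f"residue {i}: nonstandard residue type {r.residue_type!r}")
    structure.validate()
    seq = np.zeros((L, 20))
    ang = np.zeros((L, N_ANGLE_CHANNELS))
    valid = np.zeros((L, N_ANGLE_CHANNELS), dtype=bool)
    res = structure.residues
    for i, r in enumerate(res):
        seq[i, gt.AA3_TO_INDEX[r.residue_type]] = 1.0
        N, CA, C = r.pos("N"), r.pos("CA"), r.pos("C")
        if i > 0:
            ang[i, 0] = dihedral(res[i - 1].pos("C"), N, CA, C)
            ang[i, 5] = bond_angle(res[i - 1].pos("C"), N, CA)
            valid[i, 0] = valid[i, 5] = True
        if i < L - 1:
            Nn, CAn = res[i + 1].pos("N"), res[i + 1].pos("CA")
            ang[i, 1] = dihedral(N, CA, C, Nn)
            ang[i, 2] = dihedral(CA, C, Nn, CAn)
            ang[i, 4] = bond_angle(CA, C, Nn)
            valid[i, 1] = valid[i, 2] = valid[i, 4] = True
        ang[i, 3] = bond_angle(N, CA, C)
        valid[i, 3] = True
        for k, quad in enumerate(gt.chi_atom_names(r.residue_type)):
            try:
                pts = [r.pos(n) for n in quad]
            except KeyError as exc:
                raise ValueError(
                    f"residue {i + 1} ({r.residue_type}): missing side-chain atom {exc}"
                ) from exc
            ang[i, 6 + k] = dihedral(*pts)
            valid[i, 6 + k] = True
    ang = ang / np.pi
    ang[~valid] = 0.0
    return HelixFeatureMap(seq, _wrap(ang) * valid, valid)


def decode(fmap: HelixFeatureMap, chirality: str = "L") -> HelixStructure:
    """Rebuild an all-atom structure from a feature map.

    Deterministic; always lands in the canonical frame. ``chirality`` selects
    the sign of the fixed prochiral torsion offsets (CB placement, branch
    atoms) that are not part of the encoded channels: "L" (default) for
    natural amino acids, "D" to rebuild a mirror-image peptide from a map
    whose torsion channels were negated.
    """
    if chirality not in ("L", "D"):
        raise ValueError("chirality must be 'L' or 'D'")
    if not (np.all(np.isfinite(fmap.seq)) and np.all(np.isfinite(fmap.ang))):
        raise ValueError("feature map contains non-finite entries")
    sgn = 1.0 if chirality == "L" else -1.0
    L = fmap.length
    a = _wrap(fmap.ang) * np.pi  # radians
    phi, psi, omega = a[:, 0], a[:, 1], a[:, 2]
    tau1, tau2, tau3 = np.abs(a[:, 3]), np.abs(a[:, 4]), np.abs(a[:, 5])
    chi = a[:, 6:10]
    seq_idx = np.argmax(fmap.seq, axis=1)
    types = [gt.AA3[i] for i in seq_idx]

    residues: list[Residue] = []
    prev = None  # (N, CA, C) of previous residue
    for i in range(L):
        if i == 0:
            N = np.zeros(3)
            CA = np.array([gt.BOND_N_CA, 0.0, 0.0])
            t = tau1[0] if tau1[0] > 1e-6 else np.deg2rad(gt.ANGLE_N_CA_C)
            C = CA + gt.BOND_CA_C * np.array([-np.cos(t), np.sin(t), 0.0])
        else:
            pN, pCA, pC = prev
            N = place_atom(pN, pCA, pC, gt.BOND_C_N, tau2[i - 1], psi[i - 1])
            CA = place_atom(pCA, pC, N, gt.BOND_N_CA, tau3[i], omega[i - 1])
            C = place_atom(pC, N, CA, gt.BOND_CA_C, tau1[i], phi[i])
        O = place_atom(N, CA, C, gt.BOND_C_O, np.deg2rad(gt.ANGLE_CA_C_O), psi[i] + np.pi)
        atoms = {"N": N, "CA": CA, "C": C, "O": O}
        rtype = types[i]
        if rtype != "GLY":
            atoms["CB"] = place_atom(
                N, C, CA, gt.BOND_CA_CB,
                np.deg2rad(gt.ANGLE_C_CA_CB),
                sgn * np.deg2rad(gt.TORSION_N_C_CA_CB),
            )
            for tmpl in gt.SIDECHAINS[rtype]:
                kind, k_or_deg, offset = tmpl.torsion
                if kind == "chi":
                    tors = chi[i, int(k_or_deg) - 1] + sgn * np.deg2rad(offset)
                else:
                    tors = sgn * np.deg2rad(k_or_deg)
                refs = [atoms[n] for n in tmpl.refs]
                atoms[tmpl.name] = place_atom(
                    refs[0], refs[1], refs[2], tmpl.length, np.deg2rad(tmpl.angle), tors
                )
        rec = [
            AtomRecord(name, i + 1, rtype, atoms[name])
            for name in gt.heavy_atom_names(rtype)
        ]
        residues.append(Residue(rtype, rec))
        prev = (N, CA, C)
    return HelixStructure(residues, chirality=chirality)


def ideal_feature_map(L: int, sequence: str | None = None) -> HelixFeatureMap:
    """Feature map of a geometrically ideal alpha-helix (phi -57, psi -47,
    omega 180, ideal backbone bond angles, chi at first rotamer modes)."""
    if L < 4:
        raise ValueError("helix length must be >= 4 (torsions undefined below that)")
    if sequence is None:
        sequence = "A" * L
    if len(sequence) != L:
        raise ValueError("sequence length mismatch")
    seq = np.zeros((L, 20))
    ang = np.zeros((L, N_ANGLE_CHANNELS))
    valid = np.zeros((L, N_ANGLE_CHANNELS), dtype=bool)
    for i, aa in enumerate(sequence):
        rtype = gt.AA1_TO_3.get(aa.upper())
        if rtype is None:
            raise ValueError(f"unknown amino acid letter {aa!r}")
        seq[i, gt.AA3_TO_INDEX[rtype]] = 1.0
        ang[i, 3] = gt.ANGLE_N_CA_C / 180.0
        valid[i, 3] = True
        if i > 0:
            ang[i, 0] = IDEAL_PHI / 180.0
            ang[i, 5] = gt.ANGLE_C_N_CA / 180.0
            valid[i, 0] = valid[i, 5] = True
        if i < L - 1:
            ang[i, 1] = IDEAL_PSI / 180.0
            ang[i, 2] = IDEAL_OMEGA / 180.0
            ang[i, 4] = gt.ANGLE_CA_C_N / 180.0
            valid[i, 1] = valid[i, 2] = valid[i, 4] = True
        for k, modes in enumerate(CHI_MODES[rtype]):
            ang[i, 6 + k] = modes[0] / 180.0
            valid[i, 6 + k] = True
    return HelixFeatureMap(seq, _wrap(ang) * valid, valid)


def build_ideal_helix(L: int, sequence: str | None = None) -> HelixStructure:
    """All-atom ideal alpha-helix (decode of :func:`ideal_feature_map`)."""
    return decode(ideal_feature_map(L, sequence))
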