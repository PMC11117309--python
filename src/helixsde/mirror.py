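"""Mirror conversion of L-helices into D-peptides and chirality checks.

A D-peptide is the exact mirror image of an L-peptide: reflecting every atom
through a plane preserves all pairwise distances and bond angles while
negating every torsion, turning a right-handed L-helix into a left-handed
D-helix. The reflection plane here is z = 0, fixed for reproducibility (any
other plane differs only by a rigid motion).
"""
from __future__ import annotations

import numpy as np

from .geometry import dihedral
from .pdb_io import HelixStructure

__all__ = ["mirror", "chirality_of"]


def mirror(structure: HelixStructure) -> HelixStructure:
    """Reflect all coordinates through z = 0 and flip the chirality flag.

    Residue identities and atom names are unchanged (chirality is geometric,
    not a naming convention); applying ``mirror`` twice is the identity,
    bitwise on coordinates.
    """
    xyz = structure.coords().copy()
    xyz[:, 2] *= -1.0
    out = structure.with_coords(xyz)
    out.chirality = "D" if structure.chirality == "L" else "L"
    return out


def chirality_of(n: np.ndarray, ca: np.ndarray, c: np.ndarray, cb: np.ndarray | None) -> str:
    """Chirality of one residue from its N, CA, C, CB positions.

    Uses the sign of the improper dihedral N-CA-C-CB, which is about +120
    degrees for an L amino acid and about -120 for its D mirror image.
    Glycine (no CB) is achiral. Degenerate geometry raises ``ValueError``.
    """
    if cb is None:
        return "achiral"
    ang = dihedral(n, ca, c, cb)  # raises on collinear/degenerate input
    if abs(ang) < 1e-9:
        raise ValueError("degenerate geometry: CB lies in the backbone plane")
    return "L" if ang > 0 else "D"


def residue_chirality(structure: HelixStructure, index: int) -> str:
    """Chirality of residue ``index`` (1-based) of a structure."""
    r = structure.residues[index - 1]
    cb = r.pos("CB") if r.has("CB") else None
    return chirality_of(r.pos("N"), r.pos("CA"), r.pos("C"), cb)
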