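"""Mirror conversion and chirality: L-helix in, D-helix out.

Reflects an all-atom L-helix through the z = 0 plane: distances and bond
angles are preserved, every torsion flips sign, the right-handed helix
becomes left-handed, and every residue's improper dihedral certifies the
chirality change.
"""
import numpy as np
from scipy.spatial.distance import pdist

from helixsde import build_ideal_helix, encode, kabsch, mirror, residue_chirality

l_helix = build_ideal_helix(14, "ALKEMQRSTVWYFH")
d_helix = mirror(l_helix)

phi_l = encode(l_helix).ang[1:, 0].mean() * 180
phi_d = encode(d_helix).ang[1:, 0].mean() * 180
print(f"phi: L-helix {phi_l:+.0f} deg  ->  D-helix {phi_d:+.0f} deg (left-handed)")
print(f"residue 1 chirality: {residue_chirality(l_helix, 1)} -> {residue_chirality(d_helix, 1)}")

dist_err = np.abs(pdist(l_helix.coords()) - pdist(d_helix.coords())).max()
print(f"max pairwise-distance change under reflection: {dist_err:.1e} A")

_, _, rmsd = kabsch(l_helix.coords(), d_helix.coords())
print(f"best proper-rotation RMSD between L and D forms: {rmsd:.2f} A")
print("Nonzero RMSD despite identical distances: mirror images of a chiral")
print("molecule cannot be superposed by any rotation, which is exactly why")
print("D-peptides resist proteases built to recognize L-backbones.")
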