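"""Encode an all-atom helix into its feature map and rebuild it exactly.

Builds an ideal 14-residue alpha-helix, encodes it into the L x 30 matrix
the diffusion model operates on (20 one-hot sequence columns + 10 normalized
angle channels), decodes it back to Cartesian coordinates, and verifies the
round trip.
"""
import numpy as np

from helixsde import build_ideal_helix, decode, encode, kabsch

helix = build_ideal_helix(14, "ALKEMQRSTVWYFH")
fmap = encode(helix)

print(f"sequence            : {fmap.sequence}")
print(f"feature map shape   : {fmap.array().shape}  (residues x [one-hot | angles])")
print(f"phi of residues 2-4 : {np.round(fmap.ang[1:4, 0] * 180, 1)} deg  (ideal helix: -57)")
print(f"psi of residues 1-3 : {np.round(fmap.ang[0:3, 1] * 180, 1)} deg  (ideal helix: -47)")

rebuilt = decode(fmap)
_, _, rmsd = kabsch(rebuilt.coords(), helix.coords())
print(f"decode(encode(h)) vs h : {rmsd:.2e} A RMSD after superposition")
print("The encoding stores only angles; bond lengths are ideal, so the")
print("reconstruction is exact for structures built on the same geometry table.")
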