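"""Hotspot-conditional design of a D-peptide against a target helix.

Picks a target helix, declares three of its residues as hotspots (identity +
conformation), asks the model for 50 conditional generations in which those
entries of the feature map are pinned by replacement inpainting, mirror
converts every design into a D-peptide, and keeps the one whose hotspot
heavy atoms best superpose onto the (mirrored) target.
"""
from helixsde import (
    SamplerConfig,
    SyntheticHelixConfig,
    decode,
    design_query,
    residue_chirality,
    sample_maps,
    train,
    VESDEParams,
    write_pdb,
)
from helixsde.inpaint import spec_from_target
from helixsde.nn import ScoreNet

training = sample_maps(SyntheticHelixConfig(n_samples=500, seed=11))
model, _ = train(ScoreNet(seed=5), training, VESDEParams(),
                 epochs=60, batch_size=128, seed=7, lr=2e-3)

target = decode(sample_maps(SyntheticHelixConfig(n_samples=1, seed=404))[0])
hotspot_positions = [3, 7, 12]
spec = spec_from_target(target, hotspot_positions, "sequence_and_angles")
print(f"target sequence : {target.sequence}")
print(f"hotspots        : " + ", ".join(
    f"{target.sequence[p - 1]}{p}" for p in hotspot_positions))

result = design_query(model, target, spec, n=50,
                      sampler=SamplerConfig(n_steps=200, seed=3), mirror=True)

best = result.structure
print(f"design sequence : {best.sequence}  (hotspots preserved by construction)")
print(f"chirality       : {residue_chirality(best, 3)}-residues (mirror-converted)")
print(f"best-of-50 hotspot RMSD: {result.rmsd:.3f} A "
      f"(worst of the 50: {max(result.rmsds):.3f} A)")
write_pdb(best, "d_peptide_design.pdb")
print("A sub-Angstrom value means the D-peptide presents the three hotspot")
print("side chains in nearly the same relative geometry as the target.")
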