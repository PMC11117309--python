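"""Train the score model on synthetic helices and generate new ones.

Draws a small synthetic training set (tight Gaussian backbone angles around
ideal alpha-helix values, helix-former-biased sequences, discrete rotamers),
trains the variance-exploding-SDE score model, samples unconditionally with
the predictor-corrector solver, and compares generated and training angle
distributions channel by channel.

Desk-scale settings (~2 min); the full evaluation uses 2,000 training
helices and 500 generated samples (see scripts/acceptance.py).
"""
from helixsde import (
    SamplerConfig,
    SyntheticHelixConfig,
    VESDEParams,
    angle_distribution_report,
    decode,
    sample_feature_maps,
    sample_maps,
    train,
    write_pdb,
)
from helixsde.nn import ScoreNet

training = sample_maps(SyntheticHelixConfig(n_samples=500, seed=11))
model, trace = train(ScoreNet(seed=5), training, VESDEParams(),
                     epochs=60, batch_size=128, seed=7, lr=2e-3)
print(f"training loss: {trace[0]:.0f} (epoch 1) -> {trace[-1]:.0f} (epoch {len(trace)})")

generated = sample_feature_maps(model, 100, SamplerConfig(n_steps=300, seed=21))
ks = angle_distribution_report(generated, training, ("phi", "psi", "omega", "tau_n_ca_c"))
print("Kolmogorov-Smirnov distance, generated vs training (0 = identical):")
for channel, value in ks.items():
    print(f"  {channel:12s} {value:.3f}")

first = decode(generated[0])
write_pdb(first, "generated_helix.pdb")
print(f"first sample: {first.sequence}  -> generated_helix.pdb")
print("KS below ~0.1 on every backbone channel means the model reproduces")
print("the training distribution's torsion and bond-angle statistics.")
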