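# Methods

## The representation

A peptide of length L is an L × 30 matrix: 20 one-hot sequence columns and
10 angle channels in the fixed order φ, ψ, ω, τ(N-CA-C), τ(CA-C-N⁺¹),
τ(C⁻¹-N-CA), χ₁…χ₄, stored as angle/π so torsions live in (−1, 1] and bond
angles in [0, 1]. Channels that are undefined for a residue — φ of residue
1, ψ/ω and the inter-residue bond angle of the last residue, χ slots beyond
a residue type's inventory — hold 0 and are flagged in a validity mask that
excludes them from evaluation.

Bond lengths are **not** encoded. Decoding rebuilds the chain by sequential
natural-extension (NeRF) placement from a canonical frame (N₁ at the
origin, CA₁ on +x, C₁ in the xy-plane) using ideal lengths and, for side
chains, per-residue-type NeRF templates in which each heavy atom is placed
from an ideal length, an ideal angle, and a torsion that is either a χ
variable (plus a fixed branch offset) or a fixed planar value. Feature maps
therefore carry no global pose: decoding the same map twice gives bitwise
identical coordinates, and encode∘decode is the identity on valid channels
(tested to 1e-6).

Chirality is geometric. Prochiral fixed offsets (CB placement, branch atoms
like VAL CG2, ring ±120° positions) are stored with their L sign;
`decode(…, chirality="D")` negates them, so decoding a map with negated
torsion channels as D reproduces the mirror image exactly. The main
D-peptide path operates on structures, not maps: `mirror()` reflects
coordinates through z = 0 (fixed plane, for reproducibility), preserving
all distances and negating all torsions; the per-residue improper dihedral
N-CA-C-CB (≈ +120° for L, ≈ −120° for D) certifies chirality. Proline's
ring is built open from χ₁/χ₂ (closure to N is not enforced); it is rare in
the synthetic data (weight 0.005) and in helices generally.

## The synthetic helix distribution

The generator emulates the statistics of natural 14-residue α-helices so
the pipeline trains and evaluates with no structure download: per-residue
independent Gaussians for φ/ψ/ω with means (−57, −47, 180)° and sd
(7, 7, 3)°; backbone bond angles with means (111.0, 116.6, 121.7)° and sd
2.5°; amino-acid frequencies biased toward helix formers (A and L at 12%, E
and K near 9%, P at 0.5%); χ angles drawn from 1–3 discrete rotamer modes
per slot (subsets of −60/180/+60°, ±90° for aromatic χ₂) with 10° jitter.

What it deliberately does not model: φ/ψ covariance (real helices
anti-correlate them, which cancels axis drift — the independent model is,
if anything, *harder* to match on hotspot geometry), sequence-conformation
coupling, rotamer-library statistics, helix caps and kinks, and PDB
redundancy. Passing the distribution-level tests therefore shows the
method's machinery is correct and well-calibrated on a realistic,
narrow helix ensemble; it does not certify performance on the broader
conformational diversity of real PDB-derived helices, for which the same
pipeline applies unchanged to encoded real structures (`read_pdb` →
`encode`).

## Diffusion model

Forward process: variance-exploding SDE, x_t = x₀ + σ(t)z with
σ(t) = σ_min(σ_max/σ_min)^t, σ_min = 0.01, σ_max = 50 (normalized feature
units; exploding by design relative to the [−1, 1] feature range).
Training time is drawn t ~ U(1e−5, 1), which is uniform in log σ under the
geometric schedule.

The score estimator is a noise-conditional encoder–decoder over the residue
axis: residue-wise encoding (width 96), a 2× pooled stage (width 128) with
single-head self-attention so every residue attends to the whole helix,
upsampling with a skip connection, and Gaussian-Fourier log σ embeddings
added at each stage (~120k parameters, float32 numpy with an in-repo
reverse-mode autodiff; CPU evaluation is deterministic, so a fixed seed
reproduces training and sampling bit for bit).

Three numerical choices matter and were adopted after the plain recipe
measurably failed on this data:

1. **Centered denoiser preconditioning.** The network F is wrapped as
   x̂₀ = μ + c_skip(x−μ) + c_out·F(c_in(x−μ), σ) with per-entry data mean μ
   and scale s estimated from the training set (c_in = (σ²+s²)^{-1/2},
   c_skip = s²/(σ²+s²), c_out = σs(σ²+s²)^{-1/2}); the score is
   (x̂₀−x)/σ². This keeps the denoised estimate bounded for states off the
   data manifold — with a raw ε-prediction head the sampler stalled below
   σ ≈ 0.3 and samples exploded — and centering is essential because the
   angle channels have |mean| ≫ sd (e.g. τ ≈ 0.62 ± 0.014 in normalized
   units). Entries that are constant in the data (mask padding) get s = 0
   and are pinned to their constant.
2. **Circular re-cut of angle channels.** ω and trans χ rotamers sit at
   ±180°, the wrap point of the normalized interval, which a Gaussian
   diffusion on a linear axis cannot represent (generated ω came out
   near-uniform without this). Before the model sees the data, each angle
   entry is re-cut so the wrap falls in the emptiest histogram bin of its
   training values; the shift is stored in the checkpoint and inverted
   exactly after sampling. Nothing outside the model internals changes.
3. **Uniform-in-F loss weighting.** The training loss weights the DSM
   residual per entry by (σ²+s²)/s², which makes the effective regression
   target of the preconditioned network O(1) at every noise level (the
   exposed `dsm_loss` keeps the standard σ²-weighted form; both have the
   same per-σ minimizer).

Training uses Adam (lr 2e-3 decaying ×0.1 over the run), batch 128, and an
EMA of the weights (decay 0.999). Defaults: 100 epochs on 2,000 helices,
~1 min on one CPU.

## Sampling

Predictor–corrector integration of the reverse-time SDE on a uniform time
grid: Euler–Maruyama predictor x ← x + (σᵢ²−σᵢ₋₁²)s(x,tᵢ) + √(σᵢ²−σᵢ₋₁²)z,
then M = 1 Langevin corrector steps x ← x + εs + √(2ε)z with
ε = 2(r‖z‖/‖s‖)², r = 0.16, and a final Tweedie denoising step
x ← x + σ²s (on by default). Three sampler details:

- ‖z‖ is taken at its concentration value √D rather than the realized norm
  of the same draw that enters the update — reusing the draw correlates
  step size with noise and inflates the injected variance threefold
  (measured directly on a 1-D mixture).
- ε is computed per sample and capped at σ², since a sample near a score
  zero (density ridge) would otherwise receive an unbounded step.
- Every sample is driven by its own RNG stream spawned from the seed, so
  trajectories are mutually independent: sample i is identical whether
  drawn in a batch of 1 or 1,000, and best-of-n selections are
  prefix-consistent in n.

Sampler correctness is established against analytic scores (standard
normal, correlated Gaussian, two-component mixture) before any training
enters the picture, so sampler and model defects are separable. Samples are
never clamped during integration; angles are wrapped (period 2 in
normalized units) only at decode time.

Defaults: 1,000 steps. The distribution-level tests and the acceptance
script use 200–300 steps, which this model's accuracy supports (the
analytic-score checks pass at both settings); this is the package's
desk-scale operating point.

## Conditional design and evaluation

Replacement inpainting pins hotspot entries (one-hot identity alone, or
identity plus that row's 10 angle channels taken from the target —
`sequence_and_angles`, the default when a target is available, since the
selection criterion is conformational). The design query decodes n
conditional samples (n = 200 in the reference design protocol; 50 in
the desk-scale runs), optionally mirror-converts them, and selects by partial
RMSD: Kabsch superposition (SVD, reflection-corrected to a proper rotation)
restricted to the hotspot residues' heavy atoms, atoms paired by name.

Success tables bin each case's best RMSD into [0,1), [1,1.5), [1.5,2),
[2,5) Å and NA (≥ 5 Å; the sampler cannot fail to return a structure, so NA
is only reachable by a genuinely bad best match). Bins are half-open,
lower-inclusive. Sequence novelty is summarized as percent identity to the
nearest training sequence. Angle-distribution agreement uses the
two-sample Kolmogorov–Smirnov statistic per channel, pooled over valid
entries, after re-cutting each channel at the antipode of the training
set's circular mean — a linear KS would split the ω mode at 180° into two
spurious end-of-interval clusters.

## Problem sizes and expected numbers

The standard run trains on 2,000 synthetic helices, compares 500 generated
samples to the training set (backbone-channel KS comes out ≈ 0.02–0.05,
bound 0.15), and evaluates 30 held-out targets with best-of-50 conditional
design per setting. Under these conditions all three design settings
(L-type 3-hotspot < 1 Å, D-type 3/4-hotspot < 1.5 Å) succeed in 100% of
cases with median best RMSD ≈ 0.3 Å — far above the reference success
fractions those settings are benchmarked against, as expected on a distribution narrower than real PDB helices.

## Known limitations

- χ-channel marginals are reproduced less sharply than backbone channels
  (multimodal rotamers conditioned on residue type are the hardest part of
  the density; hotspot design is unaffected because hotspot χ values are
  conditioned, not generated).
- Helices only, L = 14 by default (the network requires even L); no
  multi-chain structures, no receptor context during generation.
- Side-chain geometry beyond χ torsions is ideal; proline ring closure is
  approximate.
- The mirror D-peptide evaluation compares mirrored designs to the mirrored
  target, which is isometric to the L comparison; matching D-designs against
  unmirrored L-geometry (cross-chirality mimicry) is a stricter task not
  scored here.
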