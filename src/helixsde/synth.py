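"""Synthetic all-atom helix generator.

Emulates the statistical structure of natural 14-residue alpha-helices so the
whole pipeline can be trained and evaluated without any structure download:
tight Gaussian backbone torsion and bond-angle distributions around ideal
helix values, amino-acid frequencies biased toward helix formers, and
discrete side-chain rotamer modes with angular jitter.

Sampling happens directly in feature-map space (the encoding is exact and
invertible, so sampling angles then decoding is equivalent to sampling
structures); every draw returns the paired structure and feature map.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geomtable as gt
from .featuremap import CHI_MODES, HelixFeatureMap, decode, ideal_feature_map
from .pdb_io import HelixStructure

__all__ = ["SyntheticHelixConfig", "sample_helices", "sample_maps", "split_train_test", "DEFAULT_SEQ_WEIGHTS"]

# helix-propensity-biased amino-acid frequencies (A/L/E/K/M enriched, P/G/C
# rare), order = geomtable.AA3; a package default, not an empirical claim
DEFAULT_SEQ_WEIGHTS: dict[str, float] = {
    "ALA": 0.120, "ARG": 0.060, "ASN": 0.040, "ASP": 0.050, "CYS": 0.010,
    "GLN": 0.050, "GLU": 0.090, "GLY": 0.015, "HIS": 0.030, "ILE": 0.060,
    "LEU": 0.120, "LYS": 0.090, "MET": 0.040, "PHE": 0.040, "PRO": 0.005,
    "SER": 0.040, "THR": 0.040, "TRP": 0.015, "TYR": 0.035, "VAL": 0.050,
}


@dataclass
class SyntheticHelixConfig:
    """Parameters of the synthetic helix distribution.

    Angles are in degrees. Defaults model a mildly thermal ideal alpha-helix:
    phi/psi sd 7 degrees, omega sd 3 degrees, backbone bond-angle sd 2.5
    degrees, chi angles at discrete rotamer modes with 10-degree jitter.
    """

    n_samples: int = 1
    length: int = 14
    backbone_means: tuple[float, float, float] = (-57.0, -47.0, 180.0)  # phi, psi, omega
    backbone_sds: tuple[float, float, float] = (7.0, 7.0, 3.0)
    bond_angle_means: tuple[float, float, float] = (
        gt.ANGLE_N_CA_C, gt.ANGLE_CA_C_N, gt.ANGLE_C_N_CA,
    )
    bond_angle_sds: tuple[float, float, float] = (2.5, 2.5, 2.5)
    seq_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEQ_WEIGHTS))
    chi_jitter_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.length < 4:
            raise ValueError("length must be >= 4")
        w = np.array([self.seq_weights[aa] for aa in gt.AA3])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("seq_weights must be nonnegative and sum to 1")
        if min(self.backbone_sds) < 0 or min(self.bond_angle_sds) < 0 or self.chi_jitter_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def sample_maps(config: SyntheticHelixConfig) -> list[HelixFeatureMap]:
    """Draw feature maps from the synthetic helix distribution (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.length
    weights = np.array([config.seq_weights[aa] for aa in gt.AA3])
    weights = weights / weights.sum()
    bm = np.array(config.backbone_means)
    bs = np.array(config.backbone_sds)
    am = np.array(config.bond_angle_means)
    asd = np.array(config.bond_angle_sds)
    maps = []
    for _ in range(config.n_samples):
        seq_idx = rng.choice(20, size=L, p=weights)
        template = ideal_feature_map(L, "".join(gt.AA3_TO_1[gt.AA3[i]] for i in seq_idx))
        ang = np.zeros_like(template.ang)
        valid = template.valid
        # backbone torsions phi, psi, omega then bond angles
        ang[:, 0:3] = bm + rng.normal(size=(L, 3)) * bs
        ang[:, 3:6] = am + rng.normal(size=(L, 3)) * asd
        # chi channels: pick a discrete rotamer mode per slot, add jitter
        for i, si in enumerate(seq_idx):
            rtype = gt.AA3[si]
            for k, modes in enumerate(CHI_MODES[rtype]):
                mode = modes[rng.integers(len(modes))]
                ang[i, 6 + k] = mode + rng.normal() * config.chi_jitter_sd
        ang = ang / 180.0  # degrees -> normalized (angle/pi)
        ang = np.mod(ang + 1.0, 2.0) - 1.0
        ang = np.where(ang == -1.0, 1.0, ang)
        ang[~valid] = 0.0
        maps.append(HelixFeatureMap(template.seq, ang, valid))
    return maps


def sample_helices(config: SyntheticHelixConfig) -> list[tuple[HelixStructure, HelixFeatureMap]]:
    """Draw paired (structure, feature map) samples; reproducible given seed."""
    return [(decode(m), m) for m in sample_maps(config)]


def split_train_test(samples: list, fraction: float, seed: int = 0) -> tuple[list, list]:
    """Disjoint, exhaustive, seed-reproducible split; ``fraction`` goes to train."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(fraction * len(samples)))
    train = [samples[i] for i in order[:n_train]]
    test = [samples[i] for i in order[n_train:]]
    return train, test
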