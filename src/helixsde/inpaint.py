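"""Hotspot-conditional generation by replacement inpainting.

Hotspots — residues that matter for target recognition and receptor
activation — are pinned in the feature map (their one-hot identity and,
optionally, their angle channels from a reference geometry) and the reverse
diffusion reconstructs everything else. Conditioning is replacement-style:
at every reverse step the pinned entries are overwritten with the
forward-perturbed known values,

    x <- mask * (known + sigma(t) * z) + (1 - mask) * x,

and at t -> 0 the known values are written exactly, so hotspot identities
hold in every sample by construction.

The design query mirrors the selection protocol used for peptide design:
draw n conditional samples, decode each, measure the partial RMSD over the
hotspot residues against the target, and keep the best. With ``mirror=True``
the decoded samples and the target are both mirror-converted first
(D-peptide design path).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .featuremap import (
    ANGLE_CHANNELS,
    HelixFeatureMap,
    N_ANGLE_CHANNELS,
    decode,
    encode,
    standard_valid_mask,
)
from . import geomtable as gt
from .metrics import partial_rmsd
from .mirror import mirror as mirror_structure
from .pdb_io import HelixStructure
from .sde import SamplerConfig, ScoreModel, make_replacement_hook, pc_sample

__all__ = [
    "Hotspot",
    "HotspotSpec",
    "ConditionMask",
    "mask_from_spec",
    "inpaint_sample",
    "design_query",
    "DesignResult",
]


@dataclass
class Hotspot:
    position: int          # 1-based residue index
    residue_type: str      # 1- or 3-letter amino-acid code
    geometry: np.ndarray | None = None  # (10,) normalized angle channels

    def aa3(self) -> str:
        code = self.residue_type.upper()
        if len(code) == 1:
            code = gt.AA1_TO_3.get(code, code)
        if code not in gt.AA3_TO_INDEX:
            raise ValueError(f"unknown residue type {self.residue_type!r}")
        return code


@dataclass
class HotspotSpec:
    hotspots: list[Hotspot]
    condition_scope: str = "sequence_only"  # or "sequence_and_angles"

    def validate(self, length: int) -> None:
        if not 1 <= len(self.hotspots) <= length - 1:
            raise ValueError("need between 1 and L-1 hotspots")
        positions = [h.position for h in self.hotspots]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate hotspot positions")
        for h in self.hotspots:
            if not 1 <= h.position <= length:
                raise ValueError(f"hotspot position {h.position} outside [1, {length}]")
            h.aa3()
        if self.condition_scope not in ("sequence_only", "sequence_and_angles"):
            raise ValueError(f"unknown condition_scope {self.condition_scope!r}")

    @property
    def positions(self) -> list[int]:
        return [h.position for h in self.hotspots]

    # -- YAML round trip (list of {position, aa, phi..chi4}) ---------------
    def to_yaml(self, path: str | Path) -> None:
        items = []
        for h in self.hotspots:
            d = {"position": h.position, "aa": h.aa3()}
            if h.geometry is not None:
                d.update({c: float(v) * 180.0 for c, v in zip(ANGLE_CHANNELS, h.geometry)})
            items.append(d)
        Path(path).write_text(
            yaml.safe_dump({"condition_scope": self.condition_scope, "hotspots": items})
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HotspotSpec":
        data = yaml.safe_load(Path(path).read_text())
        hotspots = []
        for d in data["hotspots"]:
            geom = None
            if any(c in d for c in ANGLE_CHANNELS):
                geom = np.array([float(d.get(c, 0.0)) / 180.0 for c in ANGLE_CHANNELS])
            hotspots.append(Hotspot(int(d["position"]), str(d["aa"]), geom))
        return cls(hotspots, data.get("condition_scope", "sequence_only"))


@dataclass
class ConditionMask:
    """Binary feature-map mask plus the pinned values where mask = 1."""

    mask: np.ndarray    # (L, 20 + C) in {0, 1}
    known: np.ndarray   # (L, 20 + C), finite wherever mask = 1

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=float)
        self.known = np.asarray(self.known, dtype=float)
        if self.mask.shape != self.known.shape:
            raise ValueError("mask and known values must share a shape")
        if not np.all(np.isin(self.mask, (0.0, 1.0))):
            raise ValueError("mask entries must be 0 or 1")
        if not np.all(np.isfinite(self.known[self.mask == 1])):
            raise ValueError("known values must be finite where mask = 1")


def mask_from_spec(spec: HotspotSpec, length: int, n_angle_channels: int = N_ANGLE_CHANNELS) -> ConditionMask:
    """Build the conditioning mask for a hotspot specification.

    ``sequence_only`` pins the 20 one-hot columns of each hotspot row;
    ``sequence_and_angles`` additionally pins that row's angle channels with
    the hotspot's reference geometry (required in that scope).
    """
    spec.validate(length)
    F = 20 + n_angle_channels
    mask = np.zeros((length, F))
    known = np.zeros((length, F))
    for h in spec.hotspots:
        row = h.position - 1
        mask[row, :20] = 1.0
        known[row, gt.AA3_TO_INDEX[h.aa3()]] = 1.0
        if spec.condition_scope == "sequence_and_angles":
            if h.geometry is None:
                raise ValueError(
                    f"hotspot at position {h.position}: sequence_and_angles "
                    "conditioning requires reference geometry"
                )
            mask[row, 20:] = 1.0
            known[row, 20:] = np.asarray(h.geometry, dtype=float)
    return ConditionMask(mask, known)


def inpaint_sample(
    model: ScoreModel,
    mask: ConditionMask,
    n_samples: int,
    sampler: SamplerConfig = SamplerConfig(),
) -> list[HelixFeatureMap]:
    """Conditional sampling with replacement inpainting (seed-reproducible)."""
    L, F = mask.mask.shape
    if (L, F) != (model.net.L, model.net.F):
        raise ValueError(f"mask shape {(L, F)} does not match model {(model.net.L, model.net.F)}")
    m = mask.mask.astype(bool)
    known_z = model.to_model_space(mask.known)
    params = model.params
    hook = make_replacement_hook(m, known_z, params)
    z = pc_sample(model, (L, F), sampler, params, n_samples=n_samples, hook=hook)
    x = model.from_model_space(z)
    # exact hard replacement in feature-map coordinates
    x[:, m] = mask.known[m]
    out = []
    for xi in x:
        fm = HelixFeatureMap.from_array(xi)
        fm.valid = standard_valid_mask(fm.sequence)
        fm.ang[~fm.valid] = 0.0
        out.append(fm)
    return out


@dataclass
class DesignResult:
    structure: HelixStructure   # best-of-n decoded (possibly mirrored) design
    rmsd: float                 # its hotspot partial RMSD, Angstrom
    rmsds: list[float] = field(default_factory=list)  # all n values, sample order
    manifest: dict = field(default_factory=dict)


def spec_from_target(
    target: HelixStructure,
    positions: list[int],
    condition_scope: str = "sequence_and_angles",
) -> HotspotSpec:
    """Hotspot spec whose identities and geometry come from a target helix."""
    tmap = encode(target)
    hotspots = []
    for p in positions:
        geom = tmap.ang[p - 1].copy() if condition_scope == "sequence_and_angles" else None
        hotspots.append(Hotspot(p, target.residues[p - 1].residue_type, geom))
    return HotspotSpec(hotspots, condition_scope)


def design_query(
    model: ScoreModel,
    target: HelixStructure,
    spec: HotspotSpec,
    n: int = 200,
    sampler: SamplerConfig = SamplerConfig(),
    atom_scope: str = "heavy",
    mirror: bool = False,
) -> DesignResult:
    """Best-of-n hotspot-conditional design against a target helix.

    Fills in missing hotspot geometry from the target when the scope asks
    for it, draws n conditional samples, decodes them (mirror-converting
    decoded samples and target when ``mirror=True``), and returns the sample
    with the lowest hotspot partial RMSD.
    """
    L = target.length
    spec.validate(L)
    if spec.condition_scope == "sequence_and_angles":
        tmap = encode(target)
        for h in spec.hotspots:
            if h.geometry is None:
                h.geometry = tmap.ang[h.position - 1].copy()
    for h in spec.hotspots:
        if target.residues[h.position - 1].residue_type != h.aa3():
            raise ValueError(
                f"target residue {h.position} is "
                f"{target.residues[h.position - 1].residue_type}, spec says {h.aa3()}"
            )
    mask = mask_from_spec(spec, L)
    samples = inpaint_sample(model, mask, n, sampler)
    reference = mirror_structure(target) if mirror else target
    rmsds, structures = [], []
    for fm in samples:
        s = decode(fm)
        if mirror:
            s = mirror_structure(s)
        structures.append(s)
        rmsds.append(partial_rmsd(s, reference, spec.positions, atom_scope))
    best = int(np.argmin(rmsds))
    manifest = {
        "n": n,
        "positions": spec.positions,
        "condition_scope": spec.condition_scope,
        "atom_scope": atom_scope,
        "mirror": mirror,
        "sampler": {"n_steps": sampler.n_steps, "corrector_steps": sampler.corrector_steps,
                    "snr": sampler.snr, "seed": sampler.seed},
        "best_index": best,
    }
    return DesignResult(structures[best], float(rmsds[best]), [float(r) for r in rmsds], manifest)
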