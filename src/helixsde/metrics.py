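"""Evaluation protocol: partial hotspot RMSD with success-bin tables,
sequence identity against a training set, and per-channel angle-distribution
divergences between generated and training samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .featuremap import ANGLE_CHANNELS, HelixFeatureMap
from .geometry import kabsch
from .pdb_io import HelixStructure

__all__ = [
    "RMSD_BIN_LABELS",
    "EvalReport",
    "partial_rmsd",
    "bin_rmsd",
    "sequence_identity",
    "nearest_identity",
    "angle_distribution_report",
]

# half-open lower-inclusive bins; NA = RMSD >= 5 A (no successful match)
RMSD_BIN_EDGES = (0.0, 1.0, 1.5, 2.0, 5.0)
RMSD_BIN_LABELS = ("rmsd (<1, %)", "rmsd (1-1.5, %)", "rmsd (1.5-2, %)", "rmsd (2-5, %)", "NA (%)")


def _atom_selection(residue, scope: str) -> list[str]:
    if scope == "backbone":
        return ["N", "CA", "C", "O"]
    if scope == "heavy":
        return [a.atom_name for a in residue.atoms]
    raise ValueError("atom_scope must be 'backbone' or 'heavy'")


def partial_rmsd(
    generated: HelixStructure,
    target: HelixStructure,
    positions: list[int],
    atom_scope: str = "heavy",
) -> float:
    """RMSD over the atoms of the listed residues (1-based positions) after
    least-squares superposition restricted to those atoms.

    With ``atom_scope="heavy"`` residue types at the listed positions must
    match between the two structures so atoms can be paired by name;
    ``"backbone"`` pairs N/CA/C/O regardless of identity.
    """
    if not positions:
        raise ValueError("need at least one position")
    P, Q = [], []
    for pos in positions:
        rg = generated.residues[pos - 1]
        rt = target.residues[pos - 1]
        if atom_scope == "heavy" and rg.residue_type != rt.residue_type:
            raise ValueError(
                f"residue {pos}: type mismatch {rg.residue_type} vs {rt.residue_type}; "
                "use atom_scope='backbone'"
            )
        names = _atom_selection(rt if atom_scope == "heavy" else rg, atom_scope)
        missing = [n for n in names if not rg.has(n)]
        if missing:
            raise ValueError(f"residue {pos}: generated structure lacks atoms {missing}")
        for n in names:
            P.append(rg.pos(n))
            Q.append(rt.pos(n))
    _, _, r = kabsch(np.array(P), np.array(Q))
    return r


def bin_rmsd(values: list[float]) -> dict[str, float]:
    """Success-bin percentages over best-case RMSD values (Angstrom).

    Bins are [0,1), [1,1.5), [1.5,2), [2,5) and NA (>= 5); boundary values
    fall in the upper bin (half-open, lower-inclusive). Percentages sum to
    100 exactly.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("bin_rmsd needs at least one value")
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("RMSD values must be finite and nonnegative")
    counts = [
        np.sum((v >= lo) & (v < hi))
        for lo, hi in zip(RMSD_BIN_EDGES[:-1], RMSD_BIN_EDGES[1:])
    ]
    counts.append(np.sum(v >= RMSD_BIN_EDGES[-1]))
    pct = 100.0 * np.array(counts, dtype=float) / v.size
    return dict(zip(RMSD_BIN_LABELS, pct))


def sequence_identity(a: str, b: str) -> float:
    """Percent identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequence length mismatch")
    if not a:
        raise ValueError("empty sequences")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def nearest_identity(query: str, training_set: list[str]) -> float:
    """Highest percent identity between query and any training sequence."""
    if not training_set:
        raise ValueError("empty training set")
    return max(sequence_identity(query, t) for t in training_set)


def angle_distribution_report(
    generated: list[HelixFeatureMap],
    training: list[HelixFeatureMap],
    channels: tuple[str, ...] = ANGLE_CHANNELS,
) -> dict[str, float]:
    """Two-sample Kolmogorov-Smirnov statistic per angle channel, pooling
    valid entries across residues and samples.

    Torsions are circular: a KS statistic on raw normalized values would
    split a mode at +-180 degrees (omega, trans chi rotamers) into two
    spurious clusters at the ends of the interval. Each channel is therefore
    re-cut at the antipode of the training set's circular mean before the
    statistic is computed, which leaves linear channels (bond angles, far
    from the cut) unchanged.
    """
    if not generated or not training:
        raise ValueError("both sample sets must be nonempty")

    def pooled(maps, ci):
        return np.concatenate([m.ang[m.valid[:, ci], ci] for m in maps])

    out = {}
    for name in channels:
        ci = ANGLE_CHANNELS.index(name)
        g = pooled(generated, ci)
        t = pooled(training, ci)
        if g.size == 0 or t.size == 0:
            out[name] = float("nan")
            continue
        # circular mean of the training channel, in normalized units
        center = np.arctan2(np.sin(np.pi * t).mean(), np.cos(np.pi * t).mean()) / np.pi
        g = np.mod(g - center + 1.0, 2.0) - 1.0
        t = np.mod(t - center + 1.0, 2.0) - 1.0
        out[name] = float(ks_2samp(g, t).statistic)
    return out


@dataclass
class EvalReport:
    """Evaluation summary: success-bin table, identity distribution,
    per-channel angle divergences and the run manifest."""

    rmsd_bins: dict[str, float]
    identity_hist: list[float] = field(default_factory=list)
    angle_divergence: dict[str, float] = field(default_factory=dict)
    n_cases: int = 0
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.rmsd_bins.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"bin percentages sum to {total}, expected 100")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=float))

    def bins_table(self) -> pd.DataFrame:
        return pd.DataFrame([self.rmsd_bins])
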