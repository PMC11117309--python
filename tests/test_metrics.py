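"""Evaluation metrics: superposition, RMSD bins, identity, KS divergences."""
import numpy as np
import pytest

from helixsde import (
    SyntheticHelixConfig,
    angle_distribution_report,
    bin_rmsd,
    build_ideal_helix,
    kabsch,
    nearest_identity,
    partial_rmsd,
    sample_maps,
    sequence_identity,
)
from helixsde.featuremap import HelixFeatureMap
from helixsde.metrics import EvalReport, RMSD_BIN_LABELS


def quaternion_superpose_rmsd(P, Q):
    """Independent oracle: optimal-rotation RMSD via Horn's quaternion method."""
    P = P - P.mean(0)
    Q = Q - Q.mean(0)
    Sxx = P.T @ Q
    K = np.empty((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    msd = max(((P**2).sum() + (Q**2).sum() - 2.0 * lam) / len(P), 0.0)
    return float(np.sqrt(msd))


def test_kabsch_agrees_with_quaternion_oracle():
    g = np.random.default_rng(12)
    for _ in range(100):
        n = g.integers(4, 30)
        P = g.normal(size=(n, 3)) * g.uniform(0.5, 5)
        Q = g.normal(size=(n, 3)) * g.uniform(0.5, 5)
        _, _, r = kabsch(P, Q)
        assert abs(r - quaternion_superpose_rmsd(P, Q)) <= 1e-8


def test_partial_rmsd_identity_and_consistency():
    s = build_ideal_helix(14, "ALKEMQRSTVWYFH")
    assert partial_rmsd(s, s, [2, 5, 9]) == pytest.approx(0.0, abs=1e-9)
    # over all residues with heavy atoms it equals the global Kabsch RMSD
    g = np.random.default_rng(1)
    noisy = s.with_coords(s.coords() + 0.3 * g.normal(size=s.coords().shape))
    all_pos = list(range(1, 15))
    _, _, global_rmsd = kabsch(noisy.coords(), s.coords())
    assert partial_rmsd(noisy, s, all_pos, "heavy") == pytest.approx(global_rmsd, abs=1e-9)


def test_partial_rmsd_equals_direct_kabsch_on_subset():
    s = build_ideal_helix(14, "ALKEMQRSTVWYFH")
    g = np.random.default_rng(2)
    noisy = s.with_coords(s.coords() + 0.5 * g.normal(size=s.coords().shape))
    pos = [3, 7, 11]
    P = np.concatenate([np.array([a.position for a in noisy.residues[p - 1].atoms]) for p in pos])
    Q = np.concatenate([np.array([a.position for a in s.residues[p - 1].atoms]) for p in pos])
    _, _, oracle = kabsch(P, Q)
    assert partial_rmsd(noisy, s, pos, "heavy") == pytest.approx(oracle, abs=1e-12)


def test_partial_rmsd_type_mismatch_needs_backbone_scope():
    a = build_ideal_helix(6, "AAAAAA")
    b = build_ideal_helix(6, "AALAAA")
    with pytest.raises(ValueError, match="type mismatch"):
        partial_rmsd(a, b, [3])
    assert partial_rmsd(a, b, [3], "backbone") >= 0.0


def test_bin_rmsd_one_value_per_bin():
    bins = bin_rmsd([0.5, 1.2, 1.7, 3.0, 7.0])
    assert list(bins.values()) == [20.0, 20.0, 20.0, 20.0, 20.0]
    assert list(bins.keys()) == list(RMSD_BIN_LABELS)


def test_bin_rmsd_boundaries_are_lower_inclusive():
    bins = bin_rmsd([1.0, 1.5, 2.0, 5.0])
    assert bins["rmsd (<1, %)"] == 0.0
    assert bins["rmsd (1-1.5, %)"] == 25.0
    assert bins["rmsd (1.5-2, %)"] == 25.0
    assert bins["rmsd (2-5, %)"] == 25.0
    assert bins["NA (%)"] == 25.0


def test_bin_rmsd_sums_to_100_and_rejects_empty():
    g = np.random.default_rng(3)
    for _ in range(20):
        vals = np.abs(g.normal(size=g.integers(1, 50))) * 4
        assert sum(bin_rmsd(list(vals)).values()) == pytest.approx(100.0, abs=1e-9)
    with pytest.raises(ValueError):
        bin_rmsd([])


def test_sequence_identity_cases():
    assert sequence_identity("A" * 14, "A" * 14) == 100.0
    assert sequence_identity("AAAA", "AAAG") == 75.0
    assert sequence_identity("AAAA", "GGGG") == 0.0
    with pytest.raises(ValueError):
        sequence_identity("AA", "AAA")


def test_nearest_identity_is_max_over_set():
    train = ["AAAA", "AALL", "GGGG"]
    assert nearest_identity("AALL", train) == 100.0
    assert nearest_identity("AALA", train) == 75.0
    # brute force agreement
    q = "ALGA"
    assert nearest_identity(q, train) == max(sequence_identity(q, t) for t in train)


def test_ks_report_zero_on_identical_sets_and_order_invariant():
    maps = sample_maps(SyntheticHelixConfig(n_samples=40, seed=8))
    ks = angle_distribution_report(maps, maps)
    assert max(ks.values()) == 0.0
    ks2 = angle_distribution_report(list(reversed(maps)), maps)
    assert ks2 == angle_distribution_report(maps, maps)


def test_ks_detects_shifted_distribution():
    maps = sample_maps(SyntheticHelixConfig(n_samples=60, seed=8))
    shifted = []
    for m in maps:
        ang = m.ang.copy()
        ang[:, 0] = np.where(m.valid[:, 0], ang[:, 0] + 0.5, ang[:, 0])
        shifted.append(HelixFeatureMap(m.seq.copy(), ang, m.valid.copy()))
    ks = angle_distribution_report(shifted, maps)
    assert ks["phi"] > 0.95
    assert ks["psi"] == 0.0


def test_ks_is_wrap_aware():
    """A distribution straddling +-180 degrees is compared on the circle."""
    maps = sample_maps(SyntheticHelixConfig(n_samples=60, seed=8))
    # omega sits at 180: half the normalized values are near +1, half near -1;
    # flipping their sign changes nothing physically
    flipped = []
    for m in maps:
        ang = m.ang.copy()
        ang[:, 2] = np.where(m.valid[:, 2], -ang[:, 2], ang[:, 2])
        flipped.append(HelixFeatureMap(m.seq.copy(), ang, m.valid.copy()))
    ks = angle_distribution_report(flipped, maps)
    # finite-sample reflection noise only; a non-circular comparison
    # would report ~1 here
    assert ks["omega"] <= 0.1


def test_eval_report_enforces_bin_sum():
    with pytest.raises(ValueError):
        EvalReport(rmsd_bins={k: 10.0 for k in RMSD_BIN_LABELS})
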