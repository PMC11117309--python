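"""Hotspot-conditional inpainting: masks, hard constraints, design queries.

The conditional-distribution correctness check on an analytic bivariate
normal (where the true conditional is closed-form) lives in the acceptance
suite at full sample count; here a reduced version guards the mechanism.
"""
import numpy as np
import pytest

from helixsde import (
    Hotspot,
    HotspotSpec,
    SamplerConfig,
    SyntheticHelixConfig,
    VESDEParams,
    decode,
    design_query,
    inpaint_sample,
    mask_from_spec,
    sample_maps,
    sigma,
)
from helixsde.inpaint import ConditionMask, spec_from_target
from helixsde.sde import make_replacement_hook, pc_sample

FAST = SamplerConfig(n_steps=120, seed=17)


def three_hotspots(scope="sequence_only", geometry=None):
    return HotspotSpec(
        [Hotspot(2, "L", geometry), Hotspot(7, "E", geometry), Hotspot(12, "K", geometry)],
        condition_scope=scope,
    )


class TestMask:
    def test_sequence_only_pins_one_hot_columns(self):
        cm = mask_from_spec(three_hotspots(), 14)
        assert cm.mask.sum() == 3 * 20
        assert cm.known.sum() == 3  # one hot per hotspot row
        assert cm.mask[1, :20].all() and not cm.mask[1, 20:].any()
        assert not cm.mask[0].any()

    def test_sequence_and_angles_pins_thirty_columns(self):
        geom = np.zeros(10)
        cm = mask_from_spec(three_hotspots("sequence_and_angles", geom), 14)
        assert cm.mask.sum() == 3 * 30

    def test_angles_scope_requires_geometry(self):
        with pytest.raises(ValueError, match="geometry"):
            mask_from_spec(three_hotspots("sequence_and_angles"), 14)

    def test_duplicate_position_rejected(self):
        spec = HotspotSpec([Hotspot(3, "A"), Hotspot(3, "L")])
        with pytest.raises(ValueError, match="duplicate"):
            mask_from_spec(spec, 14)

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mask_from_spec(HotspotSpec([Hotspot(15, "A")]), 14)

    def test_mask_known_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ConditionMask(np.zeros((3, 30)), np.zeros((4, 30)))

    def test_yaml_round_trip(self, tmp_path):
        spec = three_hotspots("sequence_and_angles", np.linspace(-0.5, 0.5, 10))
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        spec2 = HotspotSpec.from_yaml(p)
        assert spec2.condition_scope == spec.condition_scope
        assert spec2.positions == spec.positions
        assert [h.aa3() for h in spec2.hotspots] == [h.aa3() for h in spec.hotspots]
        np.testing.assert_allclose(spec2.hotspots[0].geometry, spec.hotspots[0].geometry,
                                   atol=1e-12)


class TestInpaint:
    def test_hotspot_identities_exact_in_every_sample(self, trained_model):
        cm = mask_from_spec(three_hotspots(), 14)
        maps = inpaint_sample(trained_model, cm, 6, FAST)
        for m in maps:
            assert m.sequence[1] == "L" and m.sequence[6] == "E" and m.sequence[11] == "K"
            assert np.array_equal(m.seq[1], cm.known[1, :20])

    def test_full_mask_returns_known_map(self, trained_model):
        known = sample_maps(SyntheticHelixConfig(n_samples=1, seed=55))[0]
        cm = ConditionMask(np.ones((14, 30)), known.array())
        maps = inpaint_sample(trained_model, cm, 2, FAST)
        for m in maps:
            np.testing.assert_allclose(m.array(), known.array(), atol=1e-12)

    def test_seed_reproducible(self, trained_model):
        cm = mask_from_spec(three_hotspots(), 14)
        a = inpaint_sample(trained_model, cm, 3, FAST)
        b = inpaint_sample(trained_model, cm, 3, FAST)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.array(), mb.array())

    def test_bivariate_gaussian_conditional_mean(self):
        """Reduced analytic check: conditioning x1 = a in a rho = 0.8
        bivariate normal leaves x2 ~ N(rho a, 1 - rho^2)."""
        params = VESDEParams()
        rho, a = 0.8, 1.0
        Sig = np.array([[1.0, rho], [rho, 1.0]])

        def score(x, t):
            P = np.linalg.inv(Sig + sigma(t, params) ** 2 * np.eye(2))
            return -(x @ P.T)

        hook = make_replacement_hook(np.array([True, False]), np.array([a, 0.0]), params)
        xs = pc_sample(score, (2,), SamplerConfig(n_steps=400, seed=4, corrector_steps=3),
                       params, n_samples=1200, hook=hook)
        assert np.all(xs[:, 0] == a)
        assert xs[:, 1].mean() == pytest.approx(rho * a, abs=0.08)
        assert xs[:, 1].std() == pytest.approx(np.sqrt(1 - rho**2), rel=0.15)


class TestDesignQuery:
    @pytest.fixture(scope="class")
    def target(self):
        return decode(sample_maps(SyntheticHelixConfig(n_samples=1, seed=101))[0])

    def test_n_equals_one_matches_plain_inpaint(self, trained_model, target):
        spec = spec_from_target(target, [3, 8, 12])
        res = design_query(trained_model, target, spec, n=1, sampler=FAST)
        assert len(res.rmsds) == 1
        assert res.rmsd == res.rmsds[0]

    def test_best_of_n_is_prefix_consistent(self, trained_model, target):
        spec = spec_from_target(target, [3, 8, 12])
        r5 = design_query(trained_model, target, spec, n=5, sampler=FAST)
        r2 = design_query(trained_model, target, spec, n=2, sampler=FAST)
        assert r5.rmsds[:2] == r2.rmsds
        assert r5.rmsd <= r2.rmsd

    def test_deterministic_given_seed(self, trained_model, target):
        spec = spec_from_target(target, [3, 8, 12])
        a = design_query(trained_model, target, spec, n=3, sampler=FAST)
        b = design_query(trained_model, target, spec, n=3, sampler=FAST)
        assert a.rmsd == b.rmsd
        assert np.array_equal(a.structure.coords(), b.structure.coords())

    def test_mirror_design_is_d_chiral_and_matches_mirrored_target(self, trained_model, target):
        from helixsde import residue_chirality

        spec = spec_from_target(target, [3, 8, 12])
        res = design_query(trained_model, target, spec, n=3, sampler=FAST, mirror=True)
        s = res.structure
        non_gly = [i for i in range(1, 15) if s.residues[i - 1].residue_type != "GLY"]
        assert all(residue_chirality(s, i) == "D" for i in non_gly)
        assert res.rmsd < 5.0

    def test_spec_target_identity_mismatch_rejected(self, trained_model, target):
        spec = spec_from_target(target, [3, 8, 12])
        wrong = "A" if spec.hotspots[0].aa3() != "ALA" else "L"
        spec.hotspots[0].residue_type = wrong
        with pytest.raises(ValueError, match="spec says"):
            design_query(trained_model, target, spec, n=1, sampler=FAST)
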