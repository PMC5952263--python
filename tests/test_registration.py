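"""Transforms, the MI metric and its oracles, and serialization."""

import numpy as np
import pytest

from cordprop.image_io import ImageVolume
from cordprop.masking import BinaryMask
from cordprop.registration import (
    AffineTransform,
    BSplineTransform,
    RegistrationConfig,
    RigidTransform,
    TransformChain,
    Translation,
    couch_shift_transform,
    load_transform_chain,
    mattes_mutual_information,
    save_transform_chain,
    transform_point,
)


def bspline_oracle(transform: BSplineTransform, p: np.ndarray) -> np.ndarray:
    """Brute-force tensor-product cubic B-spline displacement at one point."""

    def basis(u, k):
        # uniform cubic B-spline basis for control offsets k = -1..2
        if k == -1:
            return (1 - u) ** 3 / 6
        if k == 0:
            return (3 * u**3 - 6 * u**2 + 4) / 6
        if k == 1:
            return (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6
        return u**3 / 6

    t = (p - transform.grid_origin) / transform.grid_spacing
    base = np.floor(t).astype(int)
    u = t - base
    disp = np.zeros(3)
    for a in range(-1, 3):
        for b in range(-1, 3):
            for c in range(-1, 3):
                w = basis(u[0], a) * basis(u[1], b) * basis(u[2], c)
                disp += w * transform.coefficients[base[0] + a, base[1] + b, base[2] + c]
    return p + disp


class TestTransforms:
    def test_identity_chain_maps_exactly(self):
        chain = TransformChain([])
        pts = np.random.default_rng(0).uniform(-100, 100, (50, 3))
        assert np.array_equal(chain.apply(pts), pts)

    def test_couch_shift_examples(self):
        assert np.allclose(
            transform_point(couch_shift_transform((0, 0, 0)), (7, 8, 9)), (7, 8, 9)
        )
        assert np.allclose(
            transform_point(couch_shift_transform((2, 0, 0)), (1, 1, 1)), (3, 1, 1)
        )

    def test_couch_shift_before_zero_bspline_is_shift_alone(self):
        bs = BSplineTransform((-50, -50, -50), 20.0, (8, 8, 8))
        chain = TransformChain([Translation((2, 0, 0)), bs])
        assert np.allclose(chain.apply(np.array([[1.0, 1.0, 1.0]])), [[3, 1, 1]])

    def test_rigid_rotation_about_centre(self):
        t = RigidTransform([0, 0, np.pi / 2, 0, 0, 0], centre=(10.0, 0.0, 0.0))
        # rotating the centre itself is a no-op
        assert np.allclose(t.apply(np.array([[10.0, 0, 0]])), [[10, 0, 0]])
        # a point 5mm right of centre goes 5mm up (right-handed z rotation)
        assert np.allclose(t.apply(np.array([[15.0, 0, 0]])), [[10, 5, 0]], atol=1e-12)

    def test_affine_identity_params_are_identity(self):
        t = AffineTransform(centre=(5, 5, 5))
        pts = np.random.default_rng(1).uniform(-20, 20, (10, 3))
        assert np.allclose(t.apply(pts), pts)

    def test_bspline_zero_coefficients_identity(self):
        bs = BSplineTransform((-50, -50, -50), 15.0, (10, 10, 10))
        pts = np.random.default_rng(2).uniform(-30, 30, (100, 3))
        assert np.allclose(bs.apply(pts), pts)

    def test_bspline_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        bs = BSplineTransform((-60, -60, -30), 17.0, (9, 9, 6))
        bs.coefficients = rng.normal(0, 3.0, size=bs.grid_shape + (3,))
        lo = bs.grid_origin + bs.grid_spacing  # full-support box
        hi = bs.grid_origin + (np.array(bs.grid_shape) - 2) * bs.grid_spacing
        pts = rng.uniform(lo + 0.1, hi - 0.1, (100, 3))
        got = bs.apply(pts)
        expect = np.array([bspline_oracle(bs, p) for p in pts])
        assert np.allclose(got, expect, atol=1e-9)

    def test_bspline_partition_of_unity(self):
        """Constant coefficient field displaces every supported point equally."""
        bs = BSplineTransform((-60, -60, -30), 15.0, (10, 10, 8))
        bs.coefficients = np.broadcast_to(
            np.array([2.0, -1.0, 0.5]), bs.grid_shape + (3,)
        ).copy()
        lo = bs.grid_origin + bs.grid_spacing
        hi = bs.grid_origin + (np.array(bs.grid_shape) - 2) * bs.grid_spacing
        pts = np.random.default_rng(3).uniform(lo + 0.1, hi - 0.1, (50, 3))
        assert np.allclose(bs.apply(pts) - pts, [2.0, -1.0, 0.5], atol=1e-12)

    @pytest.mark.parametrize(
        "make",
        [
            lambda: Translation((1.5, -2.5, 3.0)),
            lambda: RigidTransform([0.1, -0.05, 0.2, 1, 2, 3], centre=(4, 5, 6)),
            lambda: AffineTransform(
                np.concatenate([np.eye(3).ravel() * 1.1, [0.5, 0.6, 0.7]]), centre=(1, 2, 3)
            ),
        ],
        ids=["translation", "rigid", "affine"],
    )
    def test_serialization_round_trip(self, make, tmp_path):
        chain = TransformChain([make()], "fixed-frame", "moving-frame")
        path = save_transform_chain(chain, tmp_path / "t.json")
        back = load_transform_chain(path)
        pts = np.random.default_rng(4).uniform(-50, 50, (20, 3))
        assert np.allclose(back.apply(pts), chain.apply(pts), atol=1e-12)
        assert back.fixed_frame == "fixed-frame"

    def test_bspline_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        bs = BSplineTransform((-40, -40, -20), 15.0, (8, 8, 5))
        bs.coefficients = rng.normal(0, 2, size=bs.grid_shape + (3,))
        chain = TransformChain([Translation((1, 2, 3)), bs])
        back = load_transform_chain(save_transform_chain(chain, tmp_path / "t.json"))
        pts = rng.uniform(-15, 15, (50, 3))
        assert np.allclose(back.apply(pts), chain.apply(pts), atol=1e-12)


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self, phantom, body_mask):
        """Dense MI of a volume with itself equals H(I) from an independent
        joint-histogram oracle."""
        kvct, _, _ = phantom
        mi = mattes_mutual_information(kvct, kvct, TransformChain([]), body_mask)
        vals = np.clip(kvct.voxels[body_mask.voxels].astype(float), -1024, 3071)
        edges = np.linspace(vals.min(), vals.max() + 1e-9, 33)
        joint, _, _ = np.histogram2d(vals, vals, bins=[edges, edges])
        p = joint / joint.sum()
        pf, pm = p.sum(axis=1), p.sum(axis=0)
        nz = p > 0
        oracle = float(np.sum(p[nz] * np.log(p[nz] / np.outer(pf, pm)[nz])))
        assert mi == pytest.approx(oracle, abs=1e-6)
        # and for a diagonal joint histogram this is the marginal entropy
        h = -np.sum(pf[pf > 0] * np.log(pf[pf > 0]))
        assert mi == pytest.approx(h, abs=1e-6)

    def test_constant_moving_volume_gives_zero_mi(self, phantom, body_mask):
        kvct, _, _ = phantom
        flat = ImageVolume(
            np.zeros_like(np.asarray(kvct.voxels, dtype=float)),
            kvct.spacing,
            kvct.origin,
        )
        mi = mattes_mutual_information(kvct, flat, TransformChain([]), body_mask)
        assert mi == pytest.approx(0.0, abs=1e-12)

    def test_permuted_volume_has_near_zero_mi(self, phantom, body_mask):
        """Voxel-wise permutation destroys spatial association; the residual
        MI is finite-sample histogram bias only."""
        kvct, _, _ = phantom
        rng = np.random.default_rng(0)
        flat = np.asarray(kvct.voxels, dtype=float).ravel()
        permuted = flat[rng.permutation(flat.size)].reshape(kvct.shape)
        vol = ImageVolume(permuted, kvct.spacing, kvct.origin)
        mi = mattes_mutual_information(kvct, vol, TransformChain([]), body_mask)
        assert body_mask.count >= 1e5 / 3  # plenty of samples for the bias bound
        assert mi < 0.05

    def test_insufficient_overlap_raises(self, phantom, body_mask):
        kvct, _, _ = phantom
        far = TransformChain([Translation((500.0, 0, 0))])
        with pytest.raises(ValueError, match="insufficient overlap"):
            mattes_mutual_information(kvct, kvct, far, body_mask)

    def test_seeded_subsampling_deterministic(self, phantom, body_mask):
        kvct, _, _ = phantom
        args = (kvct, kvct, TransformChain([]), body_mask)
        a = mattes_mutual_information(*args, samples=2000, seed=11)
        b = mattes_mutual_information(*args, samples=2000, seed=11)
        assert a == b


@pytest.fixture(scope="module")
def quick_registration(phantom, body_mask, identity_fraction):
    from cordprop.registration import register

    kvct, _, _ = phantom
    mvct, _, _, _ = identity_fraction
    cfg = RegistrationConfig(
        stages=("translation",),
        max_iterations=60,
        samples_per_iteration=2048,
        seed=21,
    )
    return kvct, mvct, cfg, register(kvct, mvct, body_mask, cfg)


class TestRegisterBehaviour:
    """Light-budget end checks of the fitting loop itself."""

    def test_metric_improves_within_each_level(self, quick_registration):
        """Within every pyramid level the best metric is no worse than the
        level's starting value (MI values are only comparable at one
        resolution, so improvement is asserted per level)."""
        import itertools

        _, _, _, chain = quick_registration
        key = lambda e: (e["stage"], e["level"])
        for (stage, level), entries in itertools.groupby(chain.log.entries, key=key):
            mis = [e["mi"] for e in entries]
            assert max(mis) >= mis[0] - 1e-12
            # and the level genuinely optimises: best beats start on the
            # finest level, where the returned parameters come from
            if level == 2:
                assert max(mis) >= mis[0]

    def test_identity_pair_recovers_near_zero_shift(self, quick_registration):
        _, _, _, chain = quick_registration
        assert np.all(np.abs(chain.transforms[0].params) < 0.5)

    def test_same_seed_bit_identical(self, quick_registration, body_mask):
        from cordprop.registration import register

        kvct, mvct, cfg, chain = quick_registration
        again = register(kvct, mvct, body_mask, cfg)
        assert np.array_equal(again.transforms[0].params, chain.transforms[0].params)


class TestRegistrationConfig:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            RegistrationConfig(bins=1)
        with pytest.raises(ValueError):
            RegistrationConfig(max_iterations=0)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            RegistrationConfig(stages=("warp9000",))

    def test_pyramid_lists_must_match(self):
        with pytest.raises(ValueError, match="pyramid"):
            RegistrationConfig(pyramid_shrink=(4, 2), pyramid_smooth=(1.0,))
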