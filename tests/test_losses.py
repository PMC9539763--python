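"""Composite objective: L1, normalized mutual information, least-squares
adversarial terms, and the network builders."""

import numpy as np
import pytest

from synthct.losses import (
    LossWeights, GeneratorSpec, DiscriminatorSpec,
    l1_loss, normalized_mutual_information, mi_loss, mi_loss_grad,
    discriminator_loss, generator_adversarial_loss, total_generator_loss,
    build_generator, build_discriminator,
)

from oracles import l1_loop, nmi_histogram, lsgan_d_loss_loop


class TestL1:
    def test_identical_planes_zero(self, rng):
        a = rng.uniform(-1, 1, (16, 16))
        assert l1_loss(a, a) == 0.0

    def test_unit_offset(self):
        assert l1_loss(np.ones((8, 8)), np.zeros((8, 8))) == 1.0

    def test_matches_loop_oracle(self, rng):
        y, g = rng.uniform(-1, 1, (12, 12)), rng.uniform(-1, 1, (12, 12))
        assert l1_loss(y, g) == pytest.approx(l1_loop(y, g), rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestNormalizedMutualInformation:
    def test_self_identity(self, rng):
        a = rng.uniform(-1, 1, (32, 32))
        assert normalized_mutual_information(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self):
        r = np.random.default_rng(42)
        a, b = r.uniform(-1, 1, 200_000), r.uniform(-1, 1, 200_000)
        assert normalized_mutual_information(a, b) < 0.05

    def test_matches_histogram_oracle(self, rng):
        a = rng.uniform(-1, 1, (20, 20))
        b = np.clip(a + rng.normal(0, 0.3, a.shape), -1, 1)
        ours = normalized_mutual_information(a, b, bins=16)
        assert ours == pytest.approx(nmi_histogram(a, b, bins=16), rel=1e-9)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            a = rng.uniform(-1, 1, (12, 12))
            b = np.clip(a * rng.uniform(0.2, 1.0) + rng.normal(0, 0.2, a.shape), -1, 1)
            ab = normalized_mutual_information(a, b)
            ba = normalized_mutual_information(b, a)
            assert ab == pytest.approx(ba, abs=1e-12)
            assert 0.0 <= ab <= 1.0

    def test_degenerate_constant_images(self):
        c = np.zeros((8, 8))
        assert normalized_mutual_information(c, c) == 1.0
        assert normalized_mutual_information(c, c + 0.5) == 0.0

    def test_rejects_empty_and_bad_bins(self):
        with pytest.raises(ValueError):
            normalized_mutual_information(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            normalized_mutual_information(np.zeros((4, 4)), np.zeros((4, 4)), bins=1)


class TestMILoss:
    def test_identical_is_zero(self, rng):
        a = rng.uniform(-1, 1, (16, 16))
        assert mi_loss(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_near_one(self):
        r = np.random.default_rng(7)
        a, b = r.uniform(-1, 1, (300, 300)), r.uniform(-1, 1, (300, 300))
        assert mi_loss(a, b) > 0.95

    def test_batch_is_mean_of_planes(self, rng):
        ys = rng.uniform(-1, 1, (3, 10, 10))
        gs = rng.uniform(-1, 1, (3, 10, 10))
        per_plane = [mi_loss(y, g) for y, g in zip(ys, gs)]
        assert mi_loss(ys, gs) == pytest.approx(np.mean(per_plane), rel=1e-12)

    def test_soft_gradient_matches_finite_differences(self, rng):
        y = rng.uniform(-1, 1, (12, 12))
        g = rng.uniform(-0.9, 0.9, (12, 12))
        _, grad = mi_loss_grad(y, g, bins=16)
        eps = 1e-7
        for flat in (0, 37, 80, 143):
            i, j = divmod(flat, 12)
            gp, gm = g.copy(), g.copy()
            gp[i, j] += eps
            gm[i, j] -= eps
            fd = (mi_loss_grad(y, gp, 16)[0] - mi_loss_grad(y, gm, 16)[0]) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, abs=1e-6)


class TestAdversarialLosses:
    def test_perfect_discriminator(self):
        assert discriminator_loss(np.ones((4, 4)), np.zeros((4, 4))) == 0.0

    def test_uncertain_discriminator(self):
        half = np.full((4, 4), 0.5)
        assert discriminator_loss(half, half) == pytest.approx(0.5)

    def test_matches_patch_loop(self, rng):
        r, f = rng.normal(0.8, 0.2, (4, 4)), rng.normal(0.2, 0.2, (4, 4))
        assert discriminator_loss(r, f) == pytest.approx(lsgan_d_loss_loop(r, f), rel=1e-12)

    @pytest.mark.parametrize("score,expected", [(1.0, 0.0), (0.0, 1.0), (0.5, 0.25)])
    def test_generator_targets_one(self, score, expected):
        assert generator_adversarial_loss(np.full((4, 4), score)) == pytest.approx(expected)

    def test_losses_minimized_at_label_values(self):
        """Grid search over constant score maps: D loss is minimized by
        (real=1, fake=0), G loss by fake=1."""
        grid = np.linspace(-0.5, 1.5, 41)
        d_vals = {(r, f): discriminator_loss(np.full((2, 2), r), np.full((2, 2), f))
                  for r in grid for f in grid}
        best = min(d_vals, key=d_vals.get)
        assert best == pytest.approx((1.0, 0.0))
        g_vals = {f: generator_adversarial_loss(np.full((2, 2), f)) for f in grid}
        assert min(g_vals, key=g_vals.get) == pytest.approx(1.0)


class TestTotalLoss:
    def test_reference_arithmetic(self):
        assert total_generator_loss(0.2, 0.01, 0.1, LossWeights()) == pytest.approx(1.7)

    def test_zero_components(self):
        assert total_generator_loss(0.0, 0.0, 0.0) == 0.0

    def test_lambda2_zero_reduces_to_pix2pix(self):
        w = LossWeights(lambda1=100.0, lambda2=0.0)
        assert total_generator_loss(0.3, 0.02, 0.9, w) == pytest.approx(0.3 + 100 * 0.02)

    def test_linear_in_each_component(self, rng):
        w = LossWeights()
        adv, l1, mi = rng.uniform(0, 1, 3)
        base = total_generator_loss(adv, l1, mi, w)
        assert total_generator_loss(adv + 1, l1, mi, w) == pytest.approx(base + 1)
        assert total_generator_loss(adv, l1 + 1, mi, w) == pytest.approx(base + w.lambda1)
        assert total_generator_loss(adv, l1, mi + 1, w) == pytest.approx(base + w.lambda2)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda1=-1.0)


class TestGeneratorNetwork:
    def test_deterministic_for_fixed_seed(self, rng):
        x = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        g1 = build_generator(GeneratorSpec(depth=3, base_channels=8), seed=5)
        g2 = build_generator(GeneratorSpec(depth=3, base_channels=8), seed=5)
        np.testing.assert_array_equal(g1(x), g2(x))
        np.testing.assert_array_equal(g1(x), g1(x))

    def test_output_shape_and_bounds(self, rng):
        g = build_generator(GeneratorSpec(depth=3, base_channels=8), seed=0)
        x = rng.uniform(-1, 1, (64, 64)).astype(np.float32)
        y = g(x)
        assert y.shape == (1, 64, 64)
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_indivisible_input_rejected(self):
        g = build_generator(GeneratorSpec(depth=3, base_channels=8), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            g(np.zeros((30, 30), dtype=np.float32))


class TestDiscriminatorNetwork:
    def test_full_scale_patch_grid(self):
        d = build_discriminator(DiscriminatorSpec(patch_grid=16, base_channels=4), seed=0)
        x = np.zeros((256, 256), dtype=np.float32)
        assert d(x, x).shape == (16, 16)

    def test_desk_scale_patch_grid(self):
        d = build_discriminator(DiscriminatorSpec(patch_grid=16, base_channels=4), seed=0)
        x = np.zeros((64, 64), dtype=np.float32)
        assert d(x, x).shape == (4, 4)

    def test_deterministic(self, rng):
        mr = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        ct = rng.uniform(-1, 1, (32, 32)).astype(np.float32)
        d1 = build_discriminator(DiscriminatorSpec(base_channels=4), seed=9)
        d2 = build_discriminator(DiscriminatorSpec(base_channels=4), seed=9)
        np.testing.assert_array_equal(d1(mr, ct), d2(mr, ct))

    def test_pair_shape_mismatch(self):
        d = build_discriminator(DiscriminatorSpec(base_channels=4), seed=0)
        with pytest.raises(ValueError, match="differ"):
            d(np.zeros((32, 32)), np.zeros((16, 16)))
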