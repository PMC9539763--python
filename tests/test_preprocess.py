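"""Intensity normalization, exterior masking, and bias-field correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synthct.volume import Volume
from synthct.preprocess import (
    mask_exterior, normalize_ct, denormalize_ct, normalize_mr,
    correct_bias_field, derive_body_mask, preprocess_case,
)


def _vol(values, modality):
    return Volume(np.asarray(values, dtype=np.float64), (1.0, 1.0, 1.0), (0, 0, 0), modality)


def _mask(values):
    return Volume(np.asarray(values, dtype=np.uint8), (1.0, 1.0, 1.0), (0, 0, 0), "MASK")


class TestCTNormalization:
    @pytest.mark.parametrize("hu,expected", [(-1000.0, -1.0), (3095.0, 1.0), (1047.5, 0.0)])
    def test_pinned_anchors(self, hu, expected):
        assert normalize_ct(hu) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("x,expected", [(-1.0, -1000.0), (1.0, 3095.0), (0.0, 1047.5)])
    def test_inverse_anchors(self, x, expected):
        assert denormalize_ct(x) == pytest.approx(expected, abs=1e-12)

    def test_round_trip_dense_grid(self):
        hu = np.linspace(-1000.0, 3095.0, 4096)
        np.testing.assert_allclose(denormalize_ct(normalize_ct(hu)), hu, atol=1e-9)

    def test_strictly_increasing(self):
        hu = np.linspace(-1000.0, 3095.0, 1000)
        assert np.all(np.diff(normalize_ct(hu)) > 0)

    def test_out_of_range_clipped(self):
        assert normalize_ct(-2000.0) == -1.0
        assert normalize_ct(5000.0) == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_ct(np.array([0.0, np.nan]))

    def test_denormalize_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            denormalize_ct(1.5)

    @given(st.floats(min_value=-1000.0, max_value=3095.0))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_property(self, hu):
        assert denormalize_ct(normalize_ct(hu)) == pytest.approx(hu, abs=1e-9)


class TestMRNormalization:
    def _mr(self, values):
        return _vol(values, "MR")

    def test_mean_maps_to_zero(self):
        # symmetric values around 500 (odd count, 0-offset included) -> mu == 500
        vals = (500.0 + np.concatenate([[0.0], np.linspace(-40.0, 40.0, 511)])).reshape(8, 8, 8)
        out, p = normalize_mr(self._mr(vals))
        assert p.mean == pytest.approx(500.0, rel=1e-12)
        assert out.values.flat[0] == pytest.approx(0.0, abs=1e-9)

    def test_interior_map_is_scaled_zscore(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(500, 50, (8, 8, 8)).clip(40)
        out, p = normalize_mr(self._mr(vals))
        np.testing.assert_allclose(
            out.values, np.clip((vals - p.mean) / p.sd / 3.0, -1.0, 1.0), rtol=1e-12
        )

    def test_three_sigma_saturates_at_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(500, 50, (10, 10, 10)).clip(40)
        out, p = normalize_mr(self._mr(vals))
        hot = vals >= p.mean + 3 * p.sd
        if hot.any():
            assert np.all(out.values[hot] == 1.0)
        assert out.values.max() <= 1.0 and out.values.min() >= -1.0

    def test_air_maps_to_minus_one(self):
        """Air (intensity < 40) sits far below the tissue mean and clips to -1."""
        vals = np.full((8, 8, 8), 1000.0)
        vals += np.arange(512).reshape(8, 8, 8) * 0.1  # non-constant tissue
        vals[0, 0, :] = 10.0  # air voxels
        out, p = normalize_mr(self._mr(vals))
        assert p.mean / p.sd > 3  # construction guarantees deep clipping
        assert np.all(out.values[0, 0, :] == -1.0)

    def test_sub_threshold_voxels_do_not_move_statistics(self):
        rng = np.random.default_rng(2)
        tissue = rng.normal(600, 80, (8, 8, 8)).clip(40)
        _, p1 = normalize_mr(self._mr(tissue))
        with_air = tissue.copy()
        with_air[:2] = 10.0
        _, p2 = normalize_mr(self._mr(with_air))
        # statistics computed over the remaining tissue only
        expect_mu = tissue[2:].mean()
        assert p2.mean == pytest.approx(expect_mu, rel=1e-12)
        assert p2.sd == pytest.approx(tissue[2:].std(), rel=1e-12)

    def test_constant_included_region_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_mr(self._mr(np.full((4, 4, 4), 100.0)))

    def test_empty_included_region_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            normalize_mr(self._mr(np.full((4, 4, 4), 5.0)))

    def test_output_always_within_unit_interval(self, rng):
        for _ in range(5):
            vals = rng.gamma(2.0, 300.0, (6, 6, 6))
            out, _ = normalize_mr(self._mr(vals))
            assert out.values.min() >= -1.0 and out.values.max() <= 1.0


class TestMaskExterior:
    def _setup(self):
        body = np.zeros((6, 6, 6), dtype=np.uint8)
        body[1:5, 1:5, 1:5] = 1
        return _mask(body)

    def test_ct_outside_to_minus_1000(self):
        body = self._setup()
        ct = _vol(np.full((6, 6, 6), 50.0), "CT")
        out = mask_exterior(ct, body)
        assert np.all(out.values[body.values == 0] == -1000.0)
        assert np.all(out.values[body.values == 1] == 50.0)

    def test_mr_outside_to_zero(self):
        body = self._setup()
        mr = _vol(np.full((6, 6, 6), 700.0), "MR")
        out = mask_exterior(mr, body)
        assert np.all(out.values[body.values == 0] == 0.0)

    def test_all_ones_mask_is_identity(self):
        ct = _vol(np.linspace(-500, 500, 216).reshape(6, 6, 6), "CT")
        out = mask_exterior(ct, _mask(np.ones((6, 6, 6))))
        np.testing.assert_array_equal(out.values, ct.values)

    def test_idempotent(self):
        body = self._setup()
        mr = _vol(np.full((6, 6, 6), 300.0), "MR")
        once = mask_exterior(mr, body)
        twice = mask_exterior(once, body)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            mask_exterior(_vol(np.zeros((4, 4, 4)), "CT"), _mask(np.ones((6, 6, 6))))

    def test_mask_as_image_rejected(self):
        with pytest.raises(ValueError):
            mask_exterior(_mask(np.ones((4, 4, 4))), _mask(np.ones((4, 4, 4))))


class TestBiasFieldCorrection:
    def _flat_phantom(self, shape=(24, 24, 24), spacing=(4.0, 4.0, 4.0)):
        body = np.zeros(shape, dtype=np.uint8)
        body[3:-3, 3:-3, 3:-3] = 1
        vals = np.where(body > 0, 400.0, 0.0)
        mr = Volume(np.asarray(vals, np.float64), spacing, (0, 0, 0), "MR")
        mask = Volume(body, spacing, (0, 0, 0), "MASK")
        return mr, mask

    def test_bias_free_input_nearly_unchanged(self):
        v, body = self._flat_phantom()
        out = correct_bias_field(v, body, sigma_mm=20.0)
        inb = body.values > 0
        np.testing.assert_allclose(out.values[inb], v.values[inb], rtol=0.01)

    def test_known_bias_cv_reduced(self):
        v, body = self._flat_phantom()
        x = np.linspace(-1, 1, 24)
        gx, gy, gz = np.meshgrid(x, x, x, indexing="ij")
        field = np.exp(np.log(1.2) * (0.6 * gx + 0.4 * gy * gy - 0.5 * gz))
        biased = v.with_values(v.values * field)
        out = correct_bias_field(biased, body, sigma_mm=20.0)
        inb = body.values > 0
        cv_before = biased.values[inb].std() / biased.values[inb].mean()
        cv_after = out.values[inb].std() / out.values[inb].mean()
        assert cv_after <= 0.5 * cv_before

    def test_mean_preserved_and_exterior_untouched(self):
        v, body = self._flat_phantom()
        x = np.linspace(-1, 1, 24)
        field = np.exp(0.15 * x)[:, None, None]
        biased = v.with_values(v.values * field)
        out = correct_bias_field(biased, body, sigma_mm=20.0)
        inb = body.values > 0
        assert out.values[inb].mean() == pytest.approx(biased.values[inb].mean(), rel=1e-9)
        np.testing.assert_array_equal(out.values[~inb], biased.values[~inb])

    def test_empty_body_rejected(self):
        v, body = self._flat_phantom()
        empty = body.with_values(np.zeros_like(body.values))
        with pytest.raises(ValueError, match="empty"):
            correct_bias_field(v, empty)


class TestDeriveBodyMask:
    def test_recovers_phantom_body(self, small_case):
        derived = derive_body_mask(small_case.ct)
        truth = small_case.body_mask.values.astype(bool)
        got = derived.values.astype(bool)
        dice = 2 * (truth & got).sum() / (truth.sum() + got.sum())
        assert dice > 0.95


class TestPreprocessCase:
    def test_normalized_ranges_and_background(self, small_case, pre_case):
        for vol in (pre_case.mr, pre_case.ct):
            assert vol.values.min() >= -1.0 and vol.values.max() <= 1.0
        outside = small_case.body_mask.values == 0
        assert np.all(pre_case.mr.values[outside] == -1.0)
        assert np.all(pre_case.ct.values[outside] == -1.0)
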