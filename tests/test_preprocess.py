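import logging

import numpy as np
import pytest

from orbitseg.phantom import default_params, generate_volume
from orbitseg.preprocess import (
    AugmentConfig,
    augment_pair,
    crop_half,
    half_offset,
    normalize_minmax,
    resample_isotropic,
    saturate_percentiles,
)
from orbitseg.types import ImageVolume


class TestNormalize:
    def test_affine_map_forced_by_min_max(self):
        out = normalize_minmax(np.array([[0.0, 5.0], [10.0, 5.0]]))
        assert np.allclose(out, [[0.0, 0.5], [1.0, 0.5]])

    def test_identity_on_unit_range(self, rng):
        img = rng.random((16, 16))
        img[0, 0], img[-1, -1] = 0.0, 1.0
        assert np.allclose(normalize_minmax(img), img)

    def test_constant_image_maps_to_zeros_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="orbitseg.preprocess"):
            out = normalize_minmax(np.full((4, 4), 7.0))
        assert np.all(out == 0.0)
        assert any("constant image" in r.message for r in caplog.records)

    def test_idempotent_and_order_preserving(self, rng):
        img = rng.normal(10, 5, (20, 20))
        once = normalize_minmax(img)
        assert np.allclose(normalize_minmax(once), once)
        flat, nflat = img.ravel(), once.ravel()
        order = np.argsort(flat)
        assert np.all(np.diff(nflat[order]) >= 0)


class TestSaturate:
    def test_outliers_pulled_to_percentile_bounds(self):
        img = np.full(100, 10.0)
        img[0], img[1] = 0.0, 1000.0
        img = img.reshape(10, 10)
        # sorting oracle: nearest order statistics at ranks 0.01/0.99*(n-1)
        s = np.sort(img.ravel())
        lo = s[round(0.01 * (s.size - 1))]
        hi = s[round(0.99 * (s.size - 1))]
        out = saturate_percentiles(img)
        assert out.min() >= lo and out.max() <= hi
        assert out.ravel()[np.argmax(img.ravel())] == hi

    def test_interior_values_unchanged(self, rng):
        img = rng.normal(0, 1, (30, 30))
        lo, hi = np.percentile(img, [1, 99])
        out = saturate_percentiles(img)
        inside = (img > lo) & (img < hi)
        assert np.array_equal(out[inside], img[inside])

    def test_monotone_and_idempotent(self, rng):
        img = rng.normal(0, 1, (25, 25))
        out = saturate_percentiles(img)
        a, b = img.ravel(), out.ravel()
        order = np.argsort(a)
        assert np.all(np.diff(b[order]) >= -1e-12)
        assert np.allclose(saturate_percentiles(out), out)

    def test_improves_ct_contrast_after_normalization(self):
        v = generate_volume(default_params("ct", seed=3, n_slices=3))
        img = v.intensities.data[1]
        ring = np.rint(v.contours[1]).astype(int)
        plain = normalize_minmax(img)
        saturated = normalize_minmax(saturate_percentiles(img))
        def contrast(x):
            ring_val = x[ring[:, 0], ring[:, 1]].mean()
            return ring_val - np.median(x)
        assert contrast(saturated) > contrast(plain)

    def test_rejects_bad_percentiles(self):
        with pytest.raises(ValueError):
            saturate_percentiles(np.ones((3, 3)), 99.0, 1.0)


class TestResample:
    def test_already_isotropic_identity(self, rng):
        vol = ImageVolume(rng.random((3, 10, 12)), (0.5, 0.5, 0.5))
        out = resample_isotropic(vol)
        assert np.array_equal(out.data, vol.data)

    def test_one_mm_doubles_in_plane_shape(self, rng):
        vol = ImageVolume(rng.random((2, 10, 12)), (0.5, 1.0, 1.0))
        out = resample_isotropic(vol)
        assert out.data.shape[0] == 2
        assert abs(out.data.shape[1] - 20) <= 1 and abs(out.data.shape[2] - 24) <= 1
        assert out.spacing_mm[1:] == (0.5, 0.5)

    def test_mask_stays_binary(self, rng):
        mask = (rng.random((2, 10, 10)) > 0.5)
        out = resample_isotropic(ImageVolume(mask, (0.5, 1.0, 1.0)), is_mask=True)
        assert out.data.dtype == bool


class TestCropHalf:
    def test_paper_resolution_halves(self):
        img = np.zeros((512, 352))
        assert crop_half(img, "left").shape == (512, 176)
        assert crop_half(img, "right").shape == (512, 176)

    def test_offset_bookkeeping_roundtrip(self, rng):
        img = rng.random((8, 10))
        for side in ("left", "right"):
            half = crop_half(img, side)
            off = half_offset(10, side)
            assert np.array_equal(img[:, off : off + half.shape[1]], half)

    def test_odd_width_floors(self):
        img = np.arange(21.0).reshape(3, 7)
        assert crop_half(img, "left").shape == (3, 3)
        assert crop_half(img, "right").shape == (3, 3)

    def test_rejects_unknown_side(self):
        with pytest.raises(ValueError):
            crop_half(np.zeros((4, 4)), "top")


class TestAugment:
    def test_identity_config(self, rng):
        img, mask = rng.random((12, 12)), rng.random((12, 12)) > 0.5
        cfg = AugmentConfig(flip_probability=0.0, rotation_range_deg=0.0)
        out_img, out_mask = augment_pair(img, mask, cfg)
        assert np.allclose(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_flip_frequency_binomial(self):
        # a left/right marker makes each flip directly observable
        cfg = AugmentConfig(flip_probability=0.5, rotation_range_deg=0.0, seed=77)
        marker = np.array([[0.0, 1.0]])
        gen = np.random.default_rng(cfg.seed)
        n = 10_000
        flips = sum(
            augment_pair(marker, marker > 0.5, cfg, rng=gen)[0][0, 0] == 1.0
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(flips / n - 0.5) < 3 * se

    def test_rotation_angle_bounded(self):
        # a single off-center pixel can move at most r*sin(range) + interp margin
        cfg = AugmentConfig(flip_probability=0.0, rotation_range_deg=10.0, seed=5)
        img = np.zeros((41, 41))
        img[20, 34] = 1.0  # radius 14 from the center
        gen = np.random.default_rng(11)
        limit = 14 * np.sin(np.deg2rad(10.0)) + 1.5
        for _ in range(200):
            _, mask = augment_pair(img, img > 0.5, cfg, rng=gen)
            (pos,) = np.argwhere(mask)
            assert np.linalg.norm(pos - [20, 34]) <= limit

    def test_centered_disk_mask_invariant_under_rotation(self):
        rr, cc = np.mgrid[0:33, 0:33]
        disk = (rr - 16) ** 2 + (cc - 16) ** 2 <= 100
        cfg = AugmentConfig(flip_probability=0.0, rotation_range_deg=10.0, seed=1)
        _, rotated = augment_pair(disk.astype(float), disk, cfg)
        # interpolation may only touch the rim
        assert abs(int(rotated.sum()) - int(disk.sum())) <= 0.02 * disk.sum()

    def test_mask_area_preserved_for_convex_masks(self, rng):
        rr, cc = np.mgrid[0:40, 0:40]
        mask = (np.abs(rr - 20) <= 8) & (np.abs(cc - 20) <= 6)
        cfg = AugmentConfig(seed=3)
        gen = np.random.default_rng(9)
        for _ in range(5):
            _, out = augment_pair(mask.astype(float), mask, cfg, rng=gen)
            assert abs(int(out.sum()) - int(mask.sum())) <= 0.02 * mask.sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((4, 4)), np.zeros((5, 5)), AugmentConfig())
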