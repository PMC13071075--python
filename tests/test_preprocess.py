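"""Preprocessing chain: resampling, HU normalization, patches, augmentation."""

import numpy as np
import pytest

from nodulenet.phantom import PhantomSpec, make_nodule_mask
from nodulenet.preprocess import (
    AugmentConfig,
    CTVolume,
    LabeledPatch,
    MaskVolume,
    ValidationError,
    augment_patch,
    clip_normalize_hu,
    extract_patch,
    resample_isotropic,
)


def ball_mask(shape, center, radius_mm, spacing):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return (d2 <= radius_mm**2).astype(np.uint8)


class TestResample:
    def test_shape_arithmetic(self, rng):
        vol = CTVolume(rng.normal(-600, 50, (100, 96, 96)).astype(np.float32), (2.0, 0.7, 0.7))
        out, _ = resample_isotropic(vol, None)
        # round(shape * spacing): (200, round(67.2)=67, 67)
        assert out.shape == (200, 67, 67)
        assert out.spacing_mm == (1.0, 1.0, 1.0)

    def test_512_slice_geometry(self):
        # classic thin-slice CT: (100, 512, 512) @ (2.0, 0.7, 0.7) -> (200, 358, 358)
        assert tuple(np.round(np.array([100, 512, 512]) * np.array([2.0, 0.7, 0.7])).astype(int)) \
            == (200, 358, 358)
        vol = CTVolume(np.zeros((10, 512, 512), np.float32), (2.0, 0.7, 0.7))
        out, _ = resample_isotropic(vol, None)
        assert out.shape == (20, 358, 358)

    def test_isotropic_input_is_identity(self, rng):
        data = rng.normal(-600, 50, (12, 12, 12)).astype(np.float32)
        vol = CTVolume(data, (1.0, 1.0, 1.0))
        out, _ = resample_isotropic(vol, None)
        assert out.shape == data.shape
        assert np.allclose(out.data, data, atol=1e-4)

    def test_mask_foreground_roughly_preserved(self):
        # 5 mm ball rasterized at (2.0, 0.7, 0.7) vs resampled to 1 mm
        spacing = (2.0, 0.7, 0.7)
        shape = (24, 40, 40)
        center = (12, 20, 20)
        mask = MaskVolume(ball_mask(shape, center, 5.0, spacing))
        vol = CTVolume(np.where(mask.data, -100, -800).astype(np.float32), spacing)
        _, rmask = resample_isotropic(vol, mask)
        vol_before = mask.foreground_count() * np.prod(spacing)
        vol_after = rmask.foreground_count() * 1.0
        assert abs(vol_after - vol_before) / vol_before < 0.20
        assert set(np.unique(rmask.data)) <= {0, 1}

    def test_rejects_bad_spacing(self):
        with pytest.raises(ValidationError):
            CTVolume(np.zeros((4, 4, 4)), (0.0, 1.0, 1.0))


class TestClipNormalize:
    def test_endpoint_and_midpoint_mapping(self):
        vol = CTVolume(np.array([[[-1000.0, -300.0, 400.0, 2000.0, -5000.0]]]), (1, 1, 1))
        out = clip_normalize_hu(vol)
        assert out.intensity_space == "normalized"
        assert np.allclose(out.data.ravel(), [0.0, 0.5, 1.0, 1.0, 0.0])

    def test_idempotence_on_clipped_input(self, rng):
        hu = rng.uniform(-1000, 400, (6, 6, 6)).astype(np.float32)
        once = clip_normalize_hu(CTVolume(hu, (1, 1, 1)))
        # renormalizing an already-normalized volume is a contract violation
        with pytest.raises(ValidationError, match="already normalized"):
            clip_normalize_hu(once)
        # but the mapping itself is idempotent on already-clipped HU values
        again = clip_normalize_hu(CTVolume(np.clip(hu, -1000, 400), (1, 1, 1)))
        assert np.allclose(once.data, again.data)


class TestExtractPatch:
    @pytest.fixture
    def norm_vol(self, rng):
        data = rng.random((80, 80, 80)).astype(np.float32)
        mask = (rng.random((80, 80, 80)) > 0.9).astype(np.uint8)
        return CTVolume(data, (1, 1, 1), "normalized"), MaskVolume(mask)

    def test_centering_convention(self, norm_vol):
        vol, mask = norm_vol
        p = extract_patch(vol, mask, (40, 41, 42))
        assert p.image.shape == (64, 64, 64)
        assert p.image[32, 32, 32] == vol.data[40, 41, 42]
        assert p.mask[32, 32, 32] == mask.data[40, 41, 42]

    def test_corner_center_pads_with_zero(self, norm_vol):
        vol, mask = norm_vol
        p = extract_patch(vol, mask, (0, 0, 0))
        assert p.image.shape == (64, 64, 64)
        # axes cover volume indices -32..31; 32 leading planes are padding
        assert np.all(p.image[:32] == 0.0) and np.all(p.mask[:32] == 0)
        assert p.image[32, 32, 32] == vol.data[0, 0, 0]
        n_pad = 64**3 - 32**3
        assert int((p.image == 0).sum()) >= n_pad

    def test_mask_crop_semantics(self, norm_vol):
        vol, mask = norm_vol
        c = (40, 40, 40)
        p = extract_patch(vol, mask, c)
        window = mask.data[8:72, 8:72, 8:72]
        assert np.array_equal(p.mask, window)

    def test_center_outside_rejected(self, norm_vol):
        vol, mask = norm_vol
        with pytest.raises(IndexError):
            extract_patch(vol, mask, (80, 0, 0))


class TestAugment:
    @pytest.fixture
    def ball_patch(self):
        spec = PhantomSpec(nodule_radius_mm=8.0, seed=5, volume_shape=(64, 64, 64),
                          noise_sigma_hu=0.0, vessel_count=0, edge_sigma=0.0)
        mask = make_nodule_mask(spec).data
        img = np.where(mask, 0.6, 0.1).astype(np.float32)
        return LabeledPatch(img, mask, label=1)

    def test_zero_probability_is_identity(self, ball_patch):
        out = augment_patch(ball_patch, AugmentConfig.identity(), seed=3)
        assert np.array_equal(out.image, ball_patch.image)
        assert np.array_equal(out.mask, ball_patch.mask)
        assert out.label == ball_patch.label

    def test_flip_is_involution(self, ball_patch):
        img = np.flip(np.flip(ball_patch.image, axis=1), axis=1)
        assert np.array_equal(img, ball_patch.image)

    def test_geometric_transforms_keep_image_mask_aligned(self, ball_patch):
        """On a two-valued phantom, thresholding the transformed image must
        reproduce the transformed mask exactly (Dice 1)."""
        cfg = AugmentConfig(p_rotate=1.0, p_flip=1.0, p_elastic=0.0, p_noise=0.0)
        for seed in range(5):
            out = augment_patch(ball_patch, cfg, seed=seed)
            thresholded = (out.image > 0.35).astype(np.uint8)
            assert np.array_equal(thresholded, out.mask)

    def test_elastic_preserves_binarity_and_rough_volume(self, ball_patch):
        cfg = AugmentConfig(p_rotate=0.0, p_flip=0.0, p_elastic=1.0, p_noise=0.0)
        before = int(ball_patch.mask.sum())
        for seed in range(3):
            out = augment_patch(ball_patch, cfg, seed=seed)
            assert set(np.unique(out.mask)) <= {0, 1}
            after = int(out.mask.sum())
            assert abs(after - before) / before < 0.15

    def test_noise_reclipped_and_mask_untouched(self, ball_patch):
        cfg = AugmentConfig(p_rotate=0.0, p_flip=0.0, p_elastic=0.0, p_noise=1.0,
                            noise_sigma=0.5)
        out = augment_patch(ball_patch, cfg, seed=11)
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0
        assert np.array_equal(out.mask, ball_patch.mask)

    def test_same_seed_reproducible(self, ball_patch):
        cfg = AugmentConfig()
        a = augment_patch(ball_patch, cfg, seed=42)
        b = augment_patch(ball_patch, cfg, seed=42)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)
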