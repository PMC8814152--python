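"""Preprocessing and augmentation contracts."""

import numpy as np
import pytest

from jawdx.augment import (AugmentConfig, central_crop_box, crop_and_resize,
                           cut_and_paste, horizontal_flip, patch_cover)
from jawdx.data import mask_bbox, survey_lesion_sizes
from jawdx.phantoms import Sample


@pytest.fixture
def config96():
    return AugmentConfig(crop_box=(0, 0, 96, 48), target_size=(96, 48))


class TestCropAndResize:
    def test_output_dims_exactly_512x256(self, lesion_sample):
        cfg = AugmentConfig(crop_box=central_crop_box(48, 96),
                            target_size=(512, 256))
        out = crop_and_resize(lesion_sample, cfg)
        assert out.image.shape == (256, 512)
        assert out.mask.shape == (256, 512)

    def test_full_frame_identity(self, lesion_sample, config96):
        out = crop_and_resize(lesion_sample, config96)
        np.testing.assert_allclose(out.image, lesion_sample.image)
        np.testing.assert_array_equal(out.mask, lesion_sample.mask)

    def test_all_ones_mask_saturates(self, healthy_sample):
        s = Sample(image=healthy_sample.image,
                   mask=np.ones_like(healthy_sample.mask), category="DC",
                   split="train", id="x")
        cfg = AugmentConfig(crop_box=(0, 0, 96, 48), target_size=(48, 24))
        out = crop_and_resize(s, cfg)
        assert out.mask.all()

    def test_clipping_lesion_raises(self, lesion_sample):
        x0, y0, x1, y1 = mask_bbox(lesion_sample.mask)
        cfg = AugmentConfig(crop_box=(x0 + 1, 0, 96, 48),
                            target_size=(48, 24))
        with pytest.raises(ValueError, match="clip"):
            crop_and_resize(lesion_sample, cfg)

    def test_flip_commutes_with_centred_crop(self, lesion_sample):
        h, w = lesion_sample.image.shape
        cfg = AugmentConfig(crop_box=(8, 4, w - 8, h - 4),
                            target_size=(64, 32))
        a = crop_and_resize(horizontal_flip(lesion_sample), cfg)
        b = horizontal_flip(crop_and_resize(lesion_sample, cfg))
        np.testing.assert_allclose(a.image, b.image, atol=1e-12)
        np.testing.assert_array_equal(a.mask, b.mask)


class TestHorizontalFlip:
    def test_involution(self, lesion_sample):
        out = horizontal_flip(horizontal_flip(lesion_sample))
        np.testing.assert_array_equal(out.image, lesion_sample.image)
        np.testing.assert_array_equal(out.mask, lesion_sample.mask)

    def test_column_index_arithmetic(self, lesion_sample):
        out = horizontal_flip(lesion_sample)
        w = lesion_sample.image.shape[1]
        for c in (0, 5, w - 1):
            np.testing.assert_array_equal(out.image[:, c],
                                          lesion_sample.image[:, w - 1 - c])

    def test_mask_sum_conserved(self, lesion_sample):
        assert horizontal_flip(lesion_sample).mask.sum() == \
            lesion_sample.mask.sum()

    def test_label_unchanged(self, lesion_sample):
        assert horizontal_flip(lesion_sample).category == \
            lesion_sample.category


class TestCutAndPaste:
    def test_pixels_inside_and_outside_mask(self, lesion_sample,
                                            healthy_sample):
        out = cut_and_paste(lesion_sample, healthy_sample)
        sel = lesion_sample.mask.astype(bool)
        np.testing.assert_array_equal(out.image[sel],
                                      lesion_sample.image[sel])
        np.testing.assert_array_equal(out.image[~sel],
                                      healthy_sample.image[~sel])

    def test_mask_mass_conserved_and_label_kept(self, lesion_sample,
                                                healthy_sample):
        out = cut_and_paste(lesion_sample, healthy_sample)
        assert out.mask.sum() == lesion_sample.mask.sum()
        assert out.category == lesion_sample.category

    def test_shape_mismatch_raises(self, lesion_sample):
        other = Sample(image=np.zeros((8, 8)), mask=np.zeros((8, 8),
                       dtype=np.uint8), category="healthy", split="train",
                       id="tiny")
        with pytest.raises(ValueError):
            cut_and_paste(lesion_sample, other)

    def test_healthy_source_rejected(self, healthy_sample):
        with pytest.raises(ValueError):
            cut_and_paste(healthy_sample, healthy_sample)


class TestPatchCover:
    @pytest.fixture
    def stats(self, lesion_sample):
        return survey_lesion_sizes([lesion_sample])

    def test_twenty_variants_half_relabeled(self, lesion_sample, stats,
                                            config96):
        rng = np.random.default_rng(0)
        variants = patch_cover(lesion_sample, stats, config96, rng)
        assert len(variants) == 20
        healthy = [v for v in variants if v.category == "healthy"]
        lesion = [v for v in variants if v.category ==
                  lesion_sample.category]
        assert len(healthy) == 10 and len(lesion) == 10
        for v in healthy:
            assert v.mask.sum() == 0
        for v in lesion:
            np.testing.assert_array_equal(v.mask, lesion_sample.mask)

    def test_lesion_cover_dims_within_survey_bounds(self, lesion_sample,
                                                    config96):
        from jawdx.data import LesionSizeStats
        bx0, by0, bx1, by1 = mask_bbox(lesion_sample.mask)
        bw, bh = bx1 - bx0, by1 - by0
        stats = LesionSizeStats(min_w=max(1, bw - 2), min_h=max(1, bh - 2),
                                max_w=bw + 6, max_h=bh + 5)
        rng = np.random.default_rng(1)
        variants = patch_cover(lesion_sample, stats, config96, rng)
        fill = config96.patch_fill
        for v in variants:
            if v.category != "healthy":
                continue
            patched = np.isclose(v.image, fill) & \
                ~np.isclose(lesion_sample.image, fill)
            ys, xs = np.nonzero(patched)
            pw = xs.max() - xs.min() + 1
            ph = ys.max() - ys.min() + 1
            assert bw <= pw <= bw + 6
            assert bh <= ph <= bh + 5
            # full occlusion: the patch rectangle contains the lesion bbox
            assert xs.min() <= bx0 and xs.max() + 1 >= bx1
            assert ys.min() <= by0 and ys.max() + 1 >= by1

    def test_healthy_cover_never_touches_lesion(self, lesion_sample, stats,
                                                config96):
        rng = np.random.default_rng(2)
        variants = patch_cover(lesion_sample, stats, config96, rng)
        sel = lesion_sample.mask.astype(bool)
        for v in variants:
            if v.category == "healthy":
                continue
            np.testing.assert_array_equal(v.image[sel],
                                          lesion_sample.image[sel])

    def test_pixels_outside_patch_unchanged(self, lesion_sample, stats,
                                            config96):
        rng = np.random.default_rng(3)
        for v in patch_cover(lesion_sample, stats, config96, rng):
            changed = v.image != lesion_sample.image
            if not changed.any():
                continue
            ys, xs = np.nonzero(changed)
            rect = np.zeros_like(changed)
            rect[ys.min():ys.max() + 1, xs.min():xs.max() + 1] = True
            assert changed[~rect].sum() == 0

    def test_healthy_input_rejected(self, healthy_sample, stats, config96):
        with pytest.raises(ValueError):
            patch_cover(healthy_sample, stats, config96,
                        np.random.default_rng(0))


class TestAugmentConfigValidation:
    def test_odd_patch_count_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(crop_box=(0, 0, 10, 10), patches_per_sample=19)

    def test_degenerate_crop_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(crop_box=(5, 5, 5, 10))
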