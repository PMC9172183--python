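"""Segmentation: overlap metrics, classical pipeline, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lungwater.segmentation import (
    AugmentationConfig,
    augment_pair,
    dice_coefficient,
    segment_lungs_classical,
    soft_jaccard_loss,
)
from lungwater.volumes import Volume


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = b[3, 3] = True
        assert dice_coefficient(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # |A| = 4, |B| = 6, |A ∩ B| = 3 -> 2*3/10 = 0.6
        a = np.zeros(10, dtype=bool)
        b = np.zeros(10, dtype=bool)
        a[:4] = True
        b[1:7] = True
        assert dice_coefficient(a, b) == pytest.approx(0.6)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3), dtype=bool)
        assert dice_coefficient(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(hnp.arrays(bool, (6, 6)), hnp.arrays(bool, (6, 6)))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        d = dice_coefficient(a, b)
        assert d == dice_coefficient(b, a)
        assert 0.0 <= d <= 1.0
        if a.any() or b.any():
            assert (d == 1.0) == np.array_equal(a, b)


class TestSoftJaccard:
    def test_perfect_overlap_is_zero(self):
        g = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert soft_jaccard_loss(g, g, eps=1.0) == pytest.approx(0.0)

    def test_no_overlap_limit_is_one(self):
        p = np.zeros((8, 8))
        g = np.ones((8, 8))
        assert soft_jaccard_loss(p, g, eps=1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_hand_evaluated_2x2(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1.0, 0.0, 0.0, 0.0])
        # 1 - (1 + 1)/(2 + 1 - 1 + 1) = 1 - 2/3
        assert soft_jaccard_loss(p, g, eps=1.0) == pytest.approx(1.0 / 3.0)

    def test_decreases_with_overlap(self):
        g = np.zeros(10)
        g[:5] = 1.0
        worse = np.roll(g, 5)  # no overlap
        better = np.roll(g, 2)  # partial overlap
        assert soft_jaccard_loss(better, g) < soft_jaccard_loss(worse, g)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            soft_jaccard_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            soft_jaccard_loss(np.full((2, 2), 1.5), np.ones((2, 2)))


class TestClassicalSegmentation:
    def test_dice_against_generator_truth(self, thorax_noise_free,
                                          lungs_noise_free):
        _, lab, _ = thorax_noise_free
        assert dice_coefficient(lungs_noise_free.right_mask,
                                lab.mask("right_lung")) >= 0.95
        assert dice_coefficient(lungs_noise_free.left_mask,
                                lab.mask("left_lung")) >= 0.95

    def test_mirrored_volume_swaps_laterality(self, thorax_noise_free,
                                              lungs_noise_free):
        vol, _, _ = thorax_noise_free
        mirrored = Volume(vol.data[:, :, ::-1].copy(), vol.spacing)
        seg = segment_lungs_classical(mirrored)
        assert dice_coefficient(seg.right_mask,
                                lungs_noise_free.left_mask[:, :, ::-1]) >= 0.95
        assert dice_coefficient(seg.left_mask,
                                lungs_noise_free.right_mask[:, :, ::-1]) >= 0.95

    def test_uniform_volume_has_no_lungs(self):
        with pytest.raises(ValueError, match="lungs not found"):
            segment_lungs_classical(Volume(np.ones((16, 16, 16))))


class TestAugmentPair:
    @staticmethod
    def _disabled():
        return AugmentationConfig(flips=False, rotate_deg=0.0,
                                  scale_range=(1.0, 1.0), blur_sigma_max=0.0,
                                  noise_sd_max=0.0)

    def test_all_disabled_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        msk = rng.random((16, 16)) > 0.5
        out_img, out_msk = augment_pair(img, msk, self._disabled(), seed=3)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_msk, msk)

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        msk = rng.random((32, 32)) > 0.7
        a = augment_pair(img, msk, seed=11)
        b = augment_pair(img, msk, seed=11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_geometric_transform_moves_image_and_mask_together(self):
        # a single bright pixel with a single-pixel mask must stay co-located
        # through whatever geometric transform is drawn
        img = np.zeros((33, 33))
        img[8, 20] = 100.0
        msk = np.zeros((33, 33), dtype=bool)
        msk[8, 20] = True
        cfg = AugmentationConfig(flips=True, rotate_deg=25.0,
                                 scale_range=(0.9, 1.1), blur_sigma_max=0.0,
                                 noise_sd_max=0.0)
        for seed in range(5):
            out_img, out_msk = augment_pair(img, msk, cfg, seed=seed)
            assert out_msk.sum() >= 1
            bright = np.unravel_index(np.argmax(out_img), out_img.shape)
            mask_pts = np.argwhere(out_msk)
            dist = np.min(np.linalg.norm(mask_pts - np.array(bright), axis=1))
            assert dist <= 1.5

    def test_flip_moves_known_pixel_to_mirror_position(self):
        img = np.zeros((9, 9))
        img[2, 3] = 1.0
        msk = img > 0
        cfg = AugmentationConfig(flips=True, rotate_deg=0.0,
                                 scale_range=(1.0, 1.0), blur_sigma_max=0.0,
                                 noise_sd_max=0.0)
        seen = set()
        for seed in range(12):
            _, out_msk = augment_pair(img, msk, cfg, seed=seed)
            seen.add(tuple(np.argwhere(out_msk)[0]))
        # the only reachable positions are the four flip images of (2, 3)
        assert seen <= {(2, 3), (6, 3), (2, 5), (6, 5)}
        assert len(seen) > 1

    def test_mask_stays_binary_under_all_transforms(self):
        rng = np.random.default_rng(5)
        img = rng.random((32, 32))
        msk = np.zeros((32, 32), dtype=bool)
        msk[10:20, 12:22] = True
        out_img, out_msk = augment_pair(img, msk, seed=9)
        assert out_msk.dtype == bool

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            augment_pair(np.zeros((4, 4)), np.zeros((5, 5), dtype=bool))

    def test_resolution_outside_recipe_range_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(target_resolution_mm=2.0)
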