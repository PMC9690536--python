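import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oomil import (
    BagBuildConfig,
    EmptyBagError,
    balance_bag,
    build_bag,
    finalize,
    grid_patch,
    threshold_filter,
)
from oomil.bag_builder import Instance, load_bags, save_bags


def _patches_from_values(values, shape=(8, 8)):
    out = []
    for i, v in enumerate(values):
        pix = np.full(shape, v, dtype=np.float32)
        out.append(Instance(pixels=pix, grid_row=i // 7, grid_col=i % 7))
    return out


class TestGridPatch:
    def test_default_grid_gives_98_patches_of_32px(self, cancer_image):
        img, _ = cancer_image
        patches = grid_patch(img, 14, 7)
        assert len(patches) == 98
        assert all(p.pixels.shape == (32, 32) for p in patches)
        assert [(p.grid_row, p.grid_col) for p in patches[:8]] == [
            (0, 0), (0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (0, 6), (1, 0),
        ]

    def test_tiling_reconstructs_image_exactly(self, cancer_image):
        img, _ = cancer_image
        patches = grid_patch(img, 14, 7)
        rows = [
            np.concatenate([patches[r * 7 + c].pixels for c in range(7)], axis=1)
            for r in range(14)
        ]
        np.testing.assert_array_equal(np.concatenate(rows, axis=0), img)

    def test_identity_grid(self, cancer_image):
        img, _ = cancer_image
        (patch,) = grid_patch(img, 1, 1)
        np.testing.assert_array_equal(patch.pixels, img)

    def test_non_divisible_image_is_center_cropped(self):
        img = np.arange(10 * 9, dtype=np.float32).reshape(10, 9) / 100
        patches = grid_patch(img, 3, 2)  # crop to 9x8, offset (0, 0)
        assert len(patches) == 6
        assert patches[0].pixels.shape == (3, 4)
        np.testing.assert_array_equal(patches[0].pixels, img[0:3, 0:4])

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            grid_patch(np.zeros((4, 4), dtype=np.float32), 14, 7)


class TestThresholdFilter:
    def test_background_removed_foreground_kept(self):
        cfg = BagBuildConfig()
        patches = _patches_from_values([0.0, 1.0])
        kept = threshold_filter(patches, cfg)
        assert [p.pixels[0, 0] for p in kept] == [1.0]

    def test_fraction_boundary_behaviour(self):
        # 30% of pixels at 0.5, rest 0: kept at min fraction 0.25, dropped at 0.35
        pix = np.zeros((10, 10), dtype=np.float32)
        pix.flat[:30] = 0.5
        patch = [Instance(pixels=pix, grid_row=0, grid_col=0)]
        kept = threshold_filter(patch, BagBuildConfig(min_foreground_fraction=0.25))
        assert len(kept) == 1
        with pytest.raises(EmptyBagError):
            threshold_filter(patch, BagBuildConfig(min_foreground_fraction=0.35))

    def test_all_background_raises_empty_bag(self):
        with pytest.raises(EmptyBagError, match="empty bag"):
            threshold_filter(_patches_from_values([0.0, 0.01]), BagBuildConfig())

    @given(frac=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None)
    def test_raising_min_fraction_never_keeps_more(self, frac):
        rng = np.random.default_rng(0)
        patches = [
            Instance(pixels=rng.random((6, 6)).astype(np.float32), grid_row=i // 7, grid_col=i % 7)
            for i in range(20)
        ]
        low = [
            p for p in patches
            if np.mean(p.pixels > 0.08) >= frac * 0.5
        ]
        high = [
            p for p in patches
            if np.mean(p.pixels > 0.08) >= frac
        ]
        assert len(high) <= len(low)


class TestBalanceBag:
    def test_surplus_trims_to_highest_foreground(self):
        cfg = BagBuildConfig(target_bag_size=70)
        patches = []
        for i in range(98):  # patch i has i+1 bright pixels of 100
            pix = np.zeros((10, 10), dtype=np.float32)
            pix.flat[: i + 1] = 1.0
            patches.append(Instance(pixels=pix, grid_row=i // 7, grid_col=i % 7))
        out = balance_bag(patches, cfg)
        assert len(out) == 70
        # the 28 lowest-foreground patches are dropped, order preserved
        kept = [int(p.pixels.sum()) for p in out]
        assert kept == list(range(29, 99))

    def test_exact_size_unchanged(self):
        cfg = BagBuildConfig(target_bag_size=5)
        patches = _patches_from_values([0.5] * 5)
        assert balance_bag(patches, cfg) == patches

    def test_deficit_fills_with_augmented_copies(self):
        cfg = BagBuildConfig(target_bag_size=70)
        patches = _patches_from_values(np.linspace(0.2, 1, 60))
        out = balance_bag(patches, cfg)
        assert len(out) == 70
        tags = [p.augmentation_tag for p in out]
        assert tags[:60] == ["none"] * 60
        assert tags[60:] == ["hflip"] * 10  # first transform, round-robin sources
        assert [p.grid_row * 7 + p.grid_col for p in out[60:]] == list(range(10))

    def test_deficit_cycles_transform_list(self):
        cfg = BagBuildConfig(target_bag_size=7)
        patches = _patches_from_values([0.5])
        out = balance_bag(patches, cfg)
        assert [p.augmentation_tag for p in out] == [
            "none", "hflip", "vflip", "rot90", "rot180", "rot270", "hflip+rot90",
        ]

    def test_augmentation_transforms_pixels(self):
        cfg = BagBuildConfig(target_bag_size=2)
        pix = np.arange(16, dtype=np.float32).reshape(4, 4) / 16
        out = balance_bag([Instance(pixels=pix, grid_row=0, grid_col=0)], cfg)
        np.testing.assert_array_equal(out[1].pixels, pix[:, ::-1])


class TestFinalize:
    def test_resizes_to_patch_side(self):
        patches = [Instance(pixels=np.random.default_rng(0).random((32, 32)).astype(np.float32), grid_row=0, grid_col=0)]
        out = finalize(patches, 224)
        assert out[0].pixels.shape == (224, 224)

    def test_already_final_is_identical(self):
        pix = np.random.default_rng(1).random((224, 224)).astype(np.float32)
        out = finalize([Instance(pixels=pix, grid_row=0, grid_col=0)], 224)
        np.testing.assert_array_equal(out[0].pixels, pix)

    def test_constant_patch_stays_constant(self):
        pix = np.full((32, 32), 0.4, dtype=np.float32)
        out = finalize([Instance(pixels=pix, grid_row=0, grid_col=0)], 224)
        np.testing.assert_allclose(out[0].pixels, 0.4, atol=1e-6)


class TestBuildBag:
    def test_default_pipeline_contract(self, cancer_image):
        img, gt = cancer_image
        bag = build_bag(img, gt.bag_label, ground_truth=gt, bag_id="b")
        assert len(bag.instances) == 70
        assert all(i.pixels.shape == (224, 224) for i in bag.instances)
        assert all(i.hidden_label is not None for i in bag.instances)
        assert max(i.hidden_label for i in bag.instances) <= bag.label

    def test_max_hidden_label_reaches_bag_label(self, cancer_image):
        # interior lesions survive the border filter, so the strongest
        # instance grade is preserved in the built bag
        img, gt = cancer_image
        bag = build_bag(img, 2, ground_truth=gt)
        assert max(i.hidden_label for i in bag.instances) == 2

    def test_all_zero_ground_truth_gives_zero_hidden_labels(self, default_synth_cfg):
        from oomil import generate_image

        img, gt = generate_image(default_synth_cfg, 0, np.random.default_rng(2))
        bag = build_bag(img, 0, ground_truth=gt)
        assert {i.hidden_label for i in bag.instances} == {0}

    def test_black_image_propagates_empty_bag(self):
        with pytest.raises(EmptyBagError):
            build_bag(np.zeros((448, 224), dtype=np.float32), 0)

    def test_invalid_label_rejected(self, cancer_image):
        with pytest.raises(ValueError):
            build_bag(cancer_image[0], 5)


def test_save_and_load_roundtrip(tmp_path, cancer_image):
    img, gt = cancer_image
    cfg = BagBuildConfig(target_bag_size=12, patch_side=32)
    bag = build_bag(img, 2, cfg, ground_truth=gt, bag_id="rt")
    save_bags([bag], tmp_path)
    (loaded,) = load_bags(tmp_path)
    assert loaded.bag_id == "rt" and loaded.label == 2
    assert len(loaded.instances) == 12
    for a, b in zip(bag.instances, loaded.instances):
        assert (a.grid_row, a.grid_col, a.augmentation_tag) == (b.grid_row, b.grid_col, b.augmentation_tag)
        assert a.hidden_label == b.hidden_label
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1 / 255 + 1e-6)
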