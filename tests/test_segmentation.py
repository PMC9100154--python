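"""Segmentation chain: thresholding, boxes, size filter, patch crops."""

import numpy as np
import pytest

from celltax.segmentation import (
    CellBox,
    SegmentationParams,
    binarize_and_clean,
    extract_patches,
    filter_boxes,
    find_cell_boxes,
    match_boxes,
    segment_image,
    to_grayscale,
)
from celltax.synthetic import SceneSpec, generate_scene


class TestGrayscale:
    def test_gray_input_is_identity(self):
        img = np.full((10, 12, 3), 137, dtype=np.uint8)
        assert np.all(to_grayscale(img) == 137)

    def test_pure_red_maps_to_luma_weight(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[:, :, 0] = 255
        assert np.all(to_grayscale(img) == round(0.299 * 255))

    def test_range_preserved(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        gray = to_grayscale(img)
        assert gray.min() >= 0 and gray.max() <= 255 and gray.dtype == np.uint8

    def test_rejects_single_channel(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((5, 5), dtype=np.uint8))


class TestBinarize:
    def test_flat_field_gives_empty_foreground(self):
        gray = np.full((80, 80), 200, dtype=np.uint8)
        assert not binarize_and_clean(gray).any()

    def test_dark_disk_is_one_component(self):
        gray = np.full((120, 120), 220, dtype=np.uint8)
        ys, xs = np.mgrid[:120, :120]
        disk = (ys - 60) ** 2 + (xs - 60) ** 2 <= 20**2
        gray[disk] = 100
        binary = binarize_and_clean(gray)
        from scipy import ndimage
        _, n = ndimage.label(binary, structure=np.ones((3, 3), bool))
        assert n == 1
        assert binary[disk].mean() > 0.9  # covers (at least the rim of) the disk

    def test_dilation_is_extensive(self):
        rng = np.random.default_rng(1)
        gray = rng.integers(0, 256, size=(100, 100), dtype=np.uint8)
        before = binarize_and_clean(
            gray, SegmentationParams(dilation_iterations=0)).sum()
        after = binarize_and_clean(
            gray, SegmentationParams(dilation_iterations=1)).sum()
        assert after >= before

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            binarize_and_clean(np.zeros((20, 20), dtype=np.uint8),
                               SegmentationParams(threshold_window=51))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(threshold_window=50)


class TestBoxes:
    def test_filled_rectangle_is_its_own_box(self):
        binary = np.zeros((200, 300), dtype=bool)
        binary[20:100, 10:130] = True
        boxes = find_cell_boxes(binary)
        assert boxes == [CellBox(x=10, y=20, w=120, h=80)]

    def test_two_blobs_two_boxes(self):
        binary = np.zeros((100, 100), dtype=bool)
        binary[5:15, 5:15] = True
        binary[50:80, 60:90] = True
        assert len(find_cell_boxes(binary)) == 2

    def test_empty_input_empty_list(self):
        assert find_cell_boxes(np.zeros((10, 10), dtype=bool)) == []

    def test_filter_boundary_semantics(self):
        keep = CellBox(x=0, y=0, w=60, h=50)     # sum 110
        drop = CellBox(x=0, y=0, w=49, h=50)     # sum 99: "less than 100"
        edge = CellBox(x=0, y=0, w=50, h=50)     # sum 100 retained
        out = filter_boxes([keep, drop, edge], 100)
        assert out == [keep, edge]

    def test_filter_idempotent_and_order_preserving(self):
        boxes = [CellBox(x=i, y=0, w=60, h=50) for i in range(5)]
        once = filter_boxes(boxes, 100)
        assert filter_boxes(once, 100) == once == boxes


class TestPatches:
    def test_crop_identity(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, size=(50, 50, 3), dtype=np.uint8)
        box = CellBox(x=0, y=0, w=10, h=10)
        [patch] = extract_patches(img, [box])
        assert np.array_equal(patch.pixels, img[:10, :10])

    def test_patch_count_matches_boxes(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        boxes = [CellBox(x=i, y=i, w=5, h=5) for i in range(3)]
        assert len(extract_patches(img, boxes)) == 3

    def test_out_of_bounds_box_rejected(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            extract_patches(img, [CellBox(x=15, y=15, w=10, h=10)])


class TestEndToEnd:
    def test_flat_image_yields_no_patches(self):
        img = np.full((120, 120, 3), 200, dtype=np.uint8)
        assert segment_image(img) == []

    def test_debris_never_survives(self):
        spec = SceneSpec(class_id=0, n_cells=4, n_debris=3, seed=21)
        img, gt = generate_scene(spec)
        patches = segment_image(img)
        for patch in patches:
            for debris in gt.debris_boxes:
                x0 = max(patch.box.x, debris.x)
                y0 = max(patch.box.y, debris.y)
                x1 = min(patch.box.x + patch.box.w, debris.x + debris.w)
                y1 = min(patch.box.y + patch.box.h, debris.y + debris.h)
                overlap = max(x1 - x0, 0) * max(y1 - y0, 0)
                assert overlap < 0.5 * debris.w * debris.h

    def test_patches_darker_than_background(self):
        spec = SceneSpec(class_id=2, n_cells=5, n_debris=0, seed=3)
        img, _ = generate_scene(spec)
        for patch in segment_image(img):
            assert patch.pixels.mean() < spec.background_level

    def test_deterministic(self):
        spec = SceneSpec(class_id=1, n_cells=5, n_debris=2, seed=8)
        img, _ = generate_scene(spec)
        a = segment_image(img)
        b = segment_image(img)
        assert [p.box for p in a] == [p.box for p in b]
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    @pytest.mark.parametrize("seed,class_id", [(31, 0), (32, 1), (33, 2), (34, 3)])
    def test_boxes_match_ground_truth(self, seed, class_id):
        spec = SceneSpec(class_id=class_id, n_cells=8, n_debris=3, seed=seed)
        img, gt = generate_scene(spec)
        patches = segment_image(img)
        tp, fp, fn = match_boxes([p.box for p in patches], gt.cell_boxes)
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9
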