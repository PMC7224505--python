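"""Threshold, clustering and active-contour segmentation against oracles."""

import numpy as np
import pytest

from conftest import disk_image, disk_mask
from fasc3d.core import BoundingBox, mask_iou
from fasc3d.phantom import PhantomSpec, generate_phantom
from fasc3d.segmentation import (
    ChanVeseParams,
    IhcSegParams,
    boxes_to_init_mask,
    mask_exterior,
    otsu_threshold,
    score_segmentation,
    segment_he,
    segment_ihc,
    segment_kmeans,
)


def brute_otsu(hist):
    """Exhaustive search over all 256 split levels."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(1, 256):
        w0 = hist[:t].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:t] * np.arange(t)).sum() / w0
        m1 = (hist[t:] * np.arange(t, 256)).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var + 1e-9:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_bimodal_histogram(self):
        hist = np.zeros(256)
        hist[10] = 50
        hist[200] = 50
        level, degenerate = otsu_threshold(hist)
        assert not degenerate
        assert 10 < level <= 200
        assert level == brute_otsu(hist)

    def test_uniform_histogram_matches_oracle(self):
        hist = np.ones(256)
        level, _ = otsu_threshold(hist)
        assert level == brute_otsu(hist)

    def test_single_level_is_degenerate(self):
        hist = np.zeros(256)
        hist[77] = 123
        level, degenerate = otsu_threshold(hist)
        assert level == 77
        assert degenerate

    def test_random_histograms_match_exhaustive_oracle(self, rng):
        for _ in range(100):
            hist = rng.integers(0, 50, size=256).astype(float)
            hist[rng.integers(0, 256)] += rng.integers(100, 500)
            level, degenerate = otsu_threshold(hist)
            if not degenerate:
                assert level == brute_otsu(hist)

    def test_agrees_with_skimage_on_an_image(self, rng):
        """Library cross-check on an 8-bit image histogram."""
        from skimage.filters import threshold_otsu

        img = np.concatenate(
            [rng.normal(60, 10, 2000), rng.normal(190, 12, 3000)]
        ).clip(0, 255).astype(np.uint8)
        hist = np.bincount(img, minlength=256).astype(float)
        level, _ = otsu_threshold(hist)
        ref = threshold_otsu(img)
        # conventions differ by the side the threshold bin falls on
        assert abs(level - ref) <= 1


class TestInitMask:
    def test_no_boxes_empty(self):
        assert not boxes_to_init_mask([], (50, 50)).any()

    def test_square_box_inscribed_disk_area(self):
        w = 40
        mask = boxes_to_init_mask(
            [BoundingBox(10, 10, w, w)], (60, 60), ChanVeseParams(init_margin=1.0)
        )
        assert mask.sum() == pytest.approx(np.pi / 4 * w * w, rel=0.05)

    def test_overlapping_boxes_form_one_component(self):
        from scipy import ndimage as ndi

        mask = boxes_to_init_mask(
            [BoundingBox(10, 10, 20, 20), BoundingBox(20, 10, 20, 20)], (60, 60)
        )
        _, n = ndi.label(mask)
        assert n == 1


class TestMaskExterior:
    def test_full_frame_unchanged(self, rng):
        img = rng.random((20, 20))
        out = mask_exterior(img, np.ones((20, 20), bool), 0.5)
        assert np.array_equal(out, img)

    def test_empty_init_uniform_fill(self, rng):
        out = mask_exterior(rng.random((20, 20)), np.zeros((20, 20), bool), 0.5)
        assert np.all(out == 0.5)

    def test_half_frame_partition(self, rng):
        img = rng.random((20, 20))
        init = np.zeros((20, 20), bool)
        init[:, :10] = True
        out = mask_exterior(img, init, 0.25)
        assert np.array_equal(out[:, :10], img[:, :10])
        assert np.all(out[:, 10:] == 0.25)


class TestSegmentIhc:
    def test_bimodal_phantom_high_iou(self):
        spec = PhantomSpec(n_slices=3, image_size=256, n_fascicles=4,
                           fascicle_radii=(9, 20), noise_sd=0.0, seed=21)
        stack, truth = generate_phantom(spec)
        ious = [
            mask_iou(segment_ihc(s.gray()), t)
            for s, t in zip(stack.slices, truth.masks("misaligned"))
        ]
        assert np.mean(ious) >= 0.95

    def test_interior_hole_filled(self):
        img = disk_image(100, [(50, 50, 20)])
        img[45:55, 45:55] = 0.9  # unstained patch inside the fascicle
        mask = segment_ihc(img)
        assert mask[48:52, 48:52].all()

    def test_constant_image_empty_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_ihc(np.full((40, 40), 0.5))
        assert not mask.any()


class TestSegmentKmeans:
    def test_bimodal_matches_otsu_partition(self):
        img = disk_image(120, [(60, 60, 25)])
        assert np.array_equal(segment_kmeans(img), segment_ihc(
            img, IhcSegParams(closing_radius=0, fill_holes=False)))

    def test_constant_image_empty(self):
        assert not segment_kmeans(np.full((30, 30), 0.4)).any()

    def test_three_level_image_matches_1d_kmeans_oracle(self):
        img = np.zeros((30, 30))
        img[:, :10], img[:, 10:20], img[:, 20:] = 0.1, 0.5, 0.9
        # 1-D k=2 optimum: enumerate the two contiguous splits
        values = [0.1, 0.5, 0.9]
        counts = [300, 300, 300]

        def wss(split):
            lo = np.repeat(values[:split], counts[:split])
            hi = np.repeat(values[split:], counts[split:])
            return ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()

        best_split = min((1, 2), key=wss)
        oracle = img < values[best_split]
        assert np.array_equal(segment_kmeans(img), oracle)


class TestSegmentHe:
    def test_clean_disk_high_iou(self):
        img = disk_image(140, [(70, 70, 25)], fg=0.45, bg=0.75)
        truth = disk_mask(140, [(70, 70, 25)])
        box = BoundingBox(70 - 32, 70 - 32, 64, 64)  # generous box
        pred = segment_he(img, [box])
        assert mask_iou(pred, truth) >= 0.95

    def test_blank_image_contour_collapses(self):
        pred = segment_he(
            np.full((100, 100), 0.7), [BoundingBox(30, 30, 40, 40)]
        )
        assert pred.sum() < 100  # empty or near-empty

    def test_two_boxed_disks_two_components(self):
        from scipy import ndimage as ndi

        img = disk_image(200, [(60, 60, 22), (140, 140, 18)], fg=0.5, bg=0.72)
        boxes = [BoundingBox(30, 30, 60, 60), BoundingBox(115, 115, 50, 50)]
        pred = segment_he(img, boxes)
        _, n = ndi.label(pred)
        assert n == 2

    def test_no_boxes_gives_empty_mask(self):
        assert not segment_he(np.full((50, 50), 0.6), []).any()

    def test_result_never_exceeds_init_ellipses(self):
        """Outside-in contract: the contour only shrinks."""
        spec = PhantomSpec(n_slices=2, image_size=256, n_fascicles=3,
                           fascicle_radii=(10, 22), stain_model="HE_like",
                           noise_sd=0.02, seed=13)
        stack, truth = generate_phantom(spec)
        boxes = truth.boxes("misaligned")[0]
        pred = segment_he(stack.slices[0].pixels, boxes)
        init = boxes_to_init_mask(boxes, pred.shape)
        assert not (pred & ~init).any()


class TestScoreSegmentation:
    def test_perfect_and_empty(self, rng):
        masks = [rng.random((20, 20)) > 0.5 for _ in range(3)]
        df = score_segmentation(masks, masks)
        assert (df["iou"] == 1.0).all()
        empty = [np.zeros((20, 20), bool) for _ in range(3)]
        df0 = score_segmentation(empty, masks)
        assert (df0["iou"] == 0.0).all()

    def test_mean_matches_loop(self, rng):
        pred = [rng.random((12, 12)) > 0.5 for _ in range(4)]
        truth = [rng.random((12, 12)) > 0.5 for _ in range(4)]
        df = score_segmentation(pred, truth)
        expected = np.mean([mask_iou(a, b) for a, b in zip(pred, truth)])
        assert df.attrs["mean_iou"] == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_segmentation([np.zeros((4, 4), bool)], [])
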