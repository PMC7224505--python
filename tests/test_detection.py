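"""Phase-coded circle detection and detection scoring conventions."""

import numpy as np
import pytest

from conftest import disk_image
from fasc3d.core import BoundingBox, box_iou
from fasc3d.detection import (
    DetectionResult,
    DetectorConfig,
    detect_hough,
    load_boxes_json,
    run_detector,
    save_boxes_json,
    score_detections,
)
from fasc3d.phantom import PhantomSpec, generate_phantom


class TestDetectHough:
    def test_blank_image_gives_nothing(self):
        assert detect_hough(np.full((100, 100), 0.8)).boxes == []

    def test_single_disk_box_size_and_position(self):
        img = disk_image(160, [(80, 70, 20)])
        res = detect_hough(img, DetectorConfig(radius_range=(7, 30)))
        assert len(res.boxes) == 1
        (box,) = res.boxes
        assert box.w == pytest.approx(40, abs=2)
        assert box.h == pytest.approx(40, abs=2)
        assert box.center[0] == pytest.approx(70, abs=2)
        assert box.center[1] == pytest.approx(80, abs=2)

    def test_two_separated_disks_both_kept(self):
        img = disk_image(220, [(60, 60, 20), (160, 160, 14)])
        res = detect_hough(img, DetectorConfig(radius_range=(7, 30)))
        assert len(res.boxes) == 2

    def test_cross_check_against_skimage_hough(self):
        """Independent oracle: classical per-radius circular Hough from
        scikit-image finds the same center and radius."""
        from skimage.feature import canny
        from skimage.transform import hough_circle, hough_circle_peaks

        img = disk_image(160, [(90, 75, 18)])
        edges = canny(img, sigma=2)
        radii = np.arange(10, 28)
        accum = hough_circle(edges, radii)
        _, cx, cy, r = hough_circle_peaks(accum, radii, total_num_peaks=1)
        res = detect_hough(img, DetectorConfig(radius_range=(7, 30)))
        (box,) = res.boxes
        assert box.center[0] == pytest.approx(cx[0], abs=2)
        assert box.center[1] == pytest.approx(cy[0], abs=2)
        assert box.w / 2 == pytest.approx(r[0], abs=2)

    def test_empty_radius_range_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(radius_range=(0, 10))

    def test_phantom_fascicles_all_matched(self):
        spec = PhantomSpec(
            n_slices=3, image_size=384, n_fascicles=5,
            fascicle_radii=(8, 24), max_aspect=1.0, noise_sd=0.02, seed=3,
        )
        stack, truth = generate_phantom(spec)
        results = run_detector(stack, DetectorConfig(radius_range=(7, 30)))
        assert len(results) == len(stack)
        score = score_detections(results, truth.boxes("misaligned"))
        assert score.fn == 0  # every fascicle >= 14 px diameter found


class TestScoreDetections:
    def _pred(self, boxes, scores=None, index=0):
        return DetectionResult(boxes, scores or [1.0] * len(boxes), index)

    def test_perfect_prediction(self):
        boxes = [BoundingBox(0, 0, 10, 10), BoundingBox(30, 30, 8, 8)]
        score = score_detections([self._pred(boxes)], [boxes])
        assert (score.precision, score.recall, score.f1) == (1.0, 1.0, 1.0)

    def test_empty_prediction_conventions(self):
        score = score_detections(
            [self._pred([])], [[BoundingBox(0, 0, 10, 10)]]
        )
        assert score.precision == 0.0
        assert score.recall == 0.0
        assert score.f1 == 0.0

    def test_below_threshold_is_fp_and_fn(self):
        pred = [self._pred([BoundingBox(5, 0, 10, 10)])]
        truth = [[BoundingBox(0, 0, 10, 10)]]
        assert box_iou(pred[0].boxes[0], truth[0][0]) == pytest.approx(1 / 3)
        score = score_detections(pred, truth, iou_threshold=0.5)
        assert (score.tp, score.fp, score.fn) == (0, 1, 1)

    def test_one_to_one_matching(self):
        # two predictions over one truth: only one can match
        truth = [[BoundingBox(0, 0, 10, 10)]]
        pred = [self._pred([BoundingBox(0, 0, 10, 10), BoundingBox(1, 0, 10, 10)])]
        score = score_detections(pred, truth)
        assert (score.tp, score.fp, score.fn) == (1, 1, 0)

    def test_matching_invariant_to_box_order(self, rng):
        truth_boxes = [
            BoundingBox(x, y, 12, 12)
            for x, y in [(0, 0), (30, 0), (0, 30), (30, 30)]
        ]
        pred_boxes = [
            BoundingBox(b.x0 + rng.integers(-2, 3), b.y0 + rng.integers(-2, 3), 12, 12)
            for b in truth_boxes
        ]
        scores = list(rng.random(len(pred_boxes)))
        base = score_detections(
            [self._pred(pred_boxes, scores)], [truth_boxes]
        )
        perm = rng.permutation(len(pred_boxes))
        shuffled = score_detections(
            [self._pred([pred_boxes[i] for i in perm],
                        [scores[i] for i in perm])],
            [list(reversed(truth_boxes))],
        )
        assert (base.tp, base.fp, base.fn) == (shuffled.tp, shuffled.fp, shuffled.fn)

    def test_f1_is_harmonic_mean_of_counts(self):
        for tp, fp, fn in [(3, 1, 2), (0, 0, 0), (5, 0, 0), (0, 4, 4)]:
            from fasc3d.detection import DetectionScore

            s = DetectionScore(tp=tp, fp=fp, fn=fn)
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert s.f1 == pytest.approx(expected)

    def test_slice_count_mismatch(self):
        with pytest.raises(ValueError):
            score_detections([self._pred([])], [[], []])


class TestExternalDetector:
    def test_json_round_trip_and_clipping(self, tmp_path):
        spec = PhantomSpec(n_slices=2, image_size=128, n_fascicles=2,
                           fascicle_radii=(8, 14), noise_sd=0.0, seed=9)
        stack, _ = generate_phantom(spec)
        results = [
            DetectionResult([BoundingBox(10, 10, 20, 20),
                             BoundingBox(115, 115, 30, 30)], [0.9, 0.4], 0),
            DetectionResult([BoundingBox(5, 5, 10, 10)], [0.7], 1),
        ]
        path = tmp_path / "boxes.json"
        save_boxes_json(path, results)
        cfg = DetectorConfig(method="external", external_path=str(path))
        loaded = run_detector(stack, cfg)
        assert len(loaded) == 2
        assert loaded[0].boxes[0].as_tuple() == (10, 10, 20, 20)
        clipped = loaded[0].boxes[1]  # partially outside the 128px frame
        assert clipped.x1 <= 128 and clipped.y1 <= 128

    def test_missing_slice_is_an_error_naming_it(self, tmp_path):
        spec = PhantomSpec(n_slices=3, image_size=64, n_fascicles=1,
                           fascicle_radii=(8, 10), noise_sd=0.0, seed=9)
        stack, _ = generate_phantom(spec)
        path = tmp_path / "boxes.json"
        save_boxes_json(path, [DetectionResult([], [], 0)])
        cfg = DetectorConfig(method="external", external_path=str(path))
        with pytest.raises(ValueError, match="slice 1"):
            run_detector(stack, cfg)

    def test_malformed_json_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"slices": [{"index": 0}]}')
        with pytest.raises(ValueError, match="malformed"):
            load_boxes_json(path)
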