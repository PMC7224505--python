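"""Per-slice fascicle detection as bounding boxes, plus detection scoring.

The built-in detector is the phase-coded circle Hough transform
(Atherton & Kerbyson): every edge pixel votes along its gradient
direction at each candidate radius, with a complex weight whose phase
encodes the radius on a log scale.  All radii share a single 2D complex
accumulator; peaks of its magnitude give circle centers and the phase at
a peak decodes the radius.  This keeps memory flat in the number of radii
and makes the radius estimate robust at the peak.

Learned detectors (e.g. an RCNN) plug in through the ``external`` method,
which reads per-slice boxes from the package's JSON interchange format;
the scoring harness treats both identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import filters
from skimage.feature import peak_local_max

from .core import BoundingBox, SliceStack, as_gray_float, box_iou

__all__ = [
    "DetectorConfig",
    "DetectionResult",
    "DetectionScore",
    "detect_hough",
    "run_detector",
    "score_detections",
    "load_boxes_json",
    "save_boxes_json",
]

BOX_CONVENTION = "0-based, half-open, (x0, y0, w, h)"


@dataclass
class DetectorConfig:
    """Configuration of the detection stage.

    ``radius_range`` is in pixels; the default minimum of 7 px reflects
    the smallest fascicle the pipeline is designed for (14 px diameter).
    ``sensitivity`` follows the usual circular-Hough convention: a circle
    is reported when its normalized accumulator peak exceeds
    ``1 - sensitivity``.  ``max_overlap`` is the box IOU above which the
    weaker of two detections is suppressed.
    """

    method: str = "hough_circles"
    radius_range: tuple[int, int] = (7, 50)
    sensitivity: float = 0.88
    max_overlap: float = 0.5
    polarity: str = "dark"  # dark fascicles on light ground (IHC-like)
    external_path: str | None = None

    def __post_init__(self) -> None:
        rmin, rmax = self.radius_range
        if not 0 < rmin <= rmax:
            raise ValueError("require 0 < radius min <= max")
        if not 0.0 < self.sensitivity < 1.0:
            raise ValueError("sensitivity must be in (0, 1)")
        if self.method not in ("hough_circles", "external"):
            raise ValueError(f"unknown detection method: {self.method}")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


@dataclass
class DetectionResult:
    """Boxes and confidences for one slice; boxes are clipped to the frame."""

    boxes: list[BoundingBox]
    scores: list[float]
    slice_index: int = 0

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.scores):
            raise ValueError("scores must align 1:1 with boxes")


@dataclass
class DetectionScore:
    """Aggregate precision/recall/F1 at a fixed IOU matching threshold."""

    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        pr = self.precision + self.recall
        self.f1 = 2 * self.precision * self.recall / pr if pr > 0 else 0.0


def _phase_code(radii: np.ndarray) -> np.ndarray:
    """Log-scale phase in [0, 2pi) assigned to each candidate radius."""
    rmin, rmax = radii[0], radii[-1]
    if rmax == rmin:
        return np.zeros_like(radii, dtype=float)
    return 2.0 * np.pi * (np.log(radii) - np.log(rmin)) / (np.log(rmax) - np.log(rmin))


def _decode_radius(phase: float, rmin: float, rmax: float) -> float:
    if rmax == rmin:
        return float(rmin)
    phase = phase % (2.0 * np.pi)
    return float(np.exp(phase / (2.0 * np.pi) * (np.log(rmax) - np.log(rmin))
                        + np.log(rmin)))


def detect_hough(img: np.ndarray, cfg: DetectorConfig | None = None) -> DetectionResult:
    """Detect circular fascicles and return their tight bounding boxes.

    A circle (cx, cy, r) maps to the box (cx - r, cy - r, 2r, 2r).  Votes
    are normalized by circumference so the peak height of a clean full
    circle is about 1 regardless of its radius; accumulator peak strength
    (clipped to [0, 1]) becomes the detection score.
    """
    cfg = cfg or DetectorConfig()
    g = as_gray_float(img)
    h, w = g.shape
    rmin, rmax = cfg.radius_range
    radii = np.arange(rmin, rmax + 1, dtype=np.float64)
    phases = _phase_code(radii)

    gy = filters.sobel_h(g)
    gx = filters.sobel_v(g)
    mag = np.hypot(gx, gy)
    mmax = mag.max()
    if mmax <= 1e-6:  # flat image: no edges, nothing to vote
        return DetectionResult([], [], 0)
    edge = mag >= 0.1 * mmax
    ey, ex = np.nonzero(edge)
    if ey.size == 0:
        return DetectionResult([], [], 0)
    # unit gradient direction; for dark objects the gradient points outward
    inward = -1.0 if cfg.polarity == "dark" else 1.0
    ux = inward * gx[ey, ex] / mag[ey, ex]
    uy = inward * gy[ey, ex] / mag[ey, ex]

    acc = np.zeros((h, w), dtype=np.complex128)
    for r, phi in zip(radii, phases):
        cx = np.rint(ex + r * ux).astype(np.intp)
        cy = np.rint(ey + r * uy).astype(np.intp)
        ok = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
        weight = np.exp(1j * phi) / (2.0 * np.pi * r)
        np.add.at(acc, (cy[ok], cx[ok]), weight)

    # consolidate votes scattered by gradient-direction quantization
    acc = ndi.gaussian_filter(acc.real, 1.0) + 1j * ndi.gaussian_filter(acc.imag, 1.0)
    strength = np.abs(acc) * (2.0 * np.pi)  # undo the smoothing's amplitude loss
    threshold = 1.0 - cfg.sensitivity
    peaks = peak_local_max(
        strength,
        min_distance=max(2, rmin // 2),
        threshold_abs=threshold,
        exclude_border=False,
    )

    candidates: list[tuple[float, BoundingBox, float, float, float]] = []
    for py, px in peaks:
        r = _decode_radius(float(np.angle(acc[py, px])), rmin, rmax)
        box = BoundingBox(px - r, py - r, 2 * r, 2 * r).clip(w, h)
        if box is None:
            continue
        candidates.append(
            (float(min(strength[py, px], 1.0)), box, float(px), float(py), r)
        )

    # greedy non-maximum suppression: drop a weaker candidate when its box
    # overlaps a kept one beyond max_overlap, or when its center falls
    # inside a kept circle (suppresses accumulator side lobes)
    candidates.sort(key=lambda c: -c[0])
    boxes: list[BoundingBox] = []
    scores: list[float] = []
    kept_circles: list[tuple[float, float, float]] = []
    for score, box, cx, cy, r in candidates:
        if any(box_iou(box, kb) > cfg.max_overlap for kb in boxes):
            continue
        if any(np.hypot(cx - kx, cy - ky) < kr
               for kx, ky, kr in kept_circles):
            continue
        boxes.append(box)
        scores.append(score)
        kept_circles.append((cx, cy, r))
    return DetectionResult(boxes, scores, 0)


def run_detector(
    stack: SliceStack, cfg: DetectorConfig | None = None
) -> list[DetectionResult]:
    """Detect fascicles on every slice of an aligned stack, in order.

    ``external`` mode reads boxes from ``cfg.external_path`` (the JSON
    interchange schema) and clips them to the image frame, providing the
    seam where a trained region-proposal network plugs in.
    """
    cfg = cfg or DetectorConfig()
    if cfg.method == "hough_circles":
        results = []
        for s in stack.slices:
            r = detect_hough(s.gray(), cfg)
            r.slice_index = s.slice_index
            results.append(r)
        return results

    if cfg.external_path is None:
        raise ValueError("external detection requires external_path")
    per_slice = load_boxes_json(cfg.external_path)
    results = []
    for s in stack.slices:
        if s.slice_index not in per_slice:
            raise ValueError(
                f"external boxes missing for slice {s.slice_index} "
                f"in {cfg.external_path}"
            )
        boxes, scores = per_slice[s.slice_index]
        clipped, kept_scores = [], []
        for b, sc in zip(boxes, scores):
            c = b.clip(s.width, s.height)
            if c is not None:
                clipped.append(c)
                kept_scores.append(sc)
        results.append(DetectionResult(clipped, kept_scores, s.slice_index))
    return results


def score_detections(
    pred: list[DetectionResult],
    truth: list[list[BoundingBox]],
    iou_threshold: float = 0.5,
) -> DetectionScore:
    """Match predictions to ground truth per slice and aggregate counts.

    Matching is greedy in descending IOU with each ground-truth box used
    at most once; a prediction counts as a true positive when its matched
    IOU meets ``iou_threshold``.  Ties are broken by higher prediction
    score, then by row-major box origin, which makes the outcome invariant
    to the order boxes were supplied in.
    """
    if len(pred) != len(truth):
        raise ValueError(
            f"slice count mismatch: {len(pred)} predictions vs {len(truth)} truths"
        )
    tp = fp = fn = 0
    for res, gt in zip(pred, truth):
        pairs = []
        for i, (pb, sc) in enumerate(zip(res.boxes, res.scores)):
            for j, tb in enumerate(gt):
                iou = box_iou(pb, tb)
                if iou >= iou_threshold:
                    pairs.append((-iou, -sc, pb.y0, pb.x0, i, j))
        pairs.sort()
        used_p: set[int] = set()
        used_t: set[int] = set()
        for _, _, _, _, i, j in pairs:
            if i in used_p or j in used_t:
                continue
            used_p.add(i)
            used_t.add(j)
        tp += len(used_p)
        fp += len(res.boxes) - len(used_p)
        fn += len(gt) - len(used_t)
    return DetectionScore(tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------


def save_boxes_json(
    path: str | Path,
    results: list[DetectionResult],
) -> None:
    """Write per-slice boxes in the package's interchange schema."""
    payload = {
        "convention": BOX_CONVENTION,
        "slices": [
            {
                "index": r.slice_index,
                "boxes": [list(b.as_tuple()) for b in r.boxes],
                "scores": list(map(float, r.scores)),
            }
            for r in results
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_boxes_json(
    path: str | Path,
) -> dict[int, tuple[list[BoundingBox], list[float]]]:
    """Read the boxes JSON schema; returns {slice_index: (boxes, scores)}."""
    try:
        payload = json.loads(Path(path).read_text())
        out = {}
        for entry in payload["slices"]:
            boxes = [BoundingBox(*b) for b in entry["boxes"]]
            scores = entry.get("scores") or [1.0] * len(boxes)
            out[int(entry["index"])] = (boxes, list(map(float, scores)))
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as err:
        raise ValueError(f"malformed boxes JSON at {path}: {err}") from err
    return out
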