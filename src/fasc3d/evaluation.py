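"""Comparison harness across pipeline configurations.

Reconstructions cannot be compared against real 3D anatomy (no volumetric
imaging precedes sectioning), so the reference is the *gold standard*: a
model built from manual registration and manual segmentation run through
the same reconstruction.  Semi-automatic arms isolate error sources:

* MRAS — Manual Registration + Automatic Segmentation,
* ARMS — Automatic Registration + Manual Segmentation,
* the fully automatic model, and
* EX — an extrusion of the first slice's manual segmentation.

With phantom data, "manual" inputs come from the generator's ground
truth.  Besides the scalar 3D IOU, a per-z-layer IOU profile is reported:
a uniform profile under a depressed IOU indicates a global displacement
of the whole fascicle group rather than reconstruction failure.  (The
profile is a diagnostic extension of this package, not part of the
original evaluation protocol.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .core import LabelVolume, SliceStack, Stain, mask_iou, volume_iou
from .detection import DetectorConfig, run_detector
from .reconstruction import ReconstructionParams, extrude_first_slice, reconstruct_block
from .registration import RegistrationSchedule, apply_transform, register_stack
from .segmentation import ChanVeseParams, IhcSegParams, segment_he, segment_ihc

__all__ = [
    "PipelineConfig",
    "STANDARD_CONFIGS",
    "compare_models",
    "automatic_masks",
    "run_matrix",
]


@dataclass(frozen=True)
class PipelineConfig:
    """One arm of the evaluation matrix."""

    registration_source: str = "automatic"  # automatic | manual
    segmentation_source: str = "automatic"  # automatic | manual
    model_kind: str = "reconstruction"  # reconstruction | extrusion

    def __post_init__(self) -> None:
        if self.registration_source not in ("automatic", "manual"):
            raise ValueError("registration_source must be automatic|manual")
        if self.segmentation_source not in ("automatic", "manual"):
            raise ValueError("segmentation_source must be automatic|manual")
        if self.model_kind not in ("reconstruction", "extrusion"):
            raise ValueError("model_kind must be reconstruction|extrusion")

    @property
    def name(self) -> str:
        key = (self.registration_source, self.segmentation_source, self.model_kind)
        return {
            ("manual", "automatic", "reconstruction"): "MRAS",
            ("automatic", "manual", "reconstruction"): "ARMS",
            ("automatic", "automatic", "reconstruction"): "automatic",
            ("manual", "manual", "extrusion"): "EX",
            ("manual", "manual", "reconstruction"): "gold",
        }.get(key, "-".join(key))


STANDARD_CONFIGS: tuple[PipelineConfig, ...] = (
    PipelineConfig("manual", "manual", "reconstruction"),  # gold
    PipelineConfig("automatic", "automatic", "reconstruction"),
    PipelineConfig("manual", "automatic", "reconstruction"),  # MRAS
    PipelineConfig("automatic", "manual", "reconstruction"),  # ARMS
    PipelineConfig("manual", "manual", "extrusion"),  # EX
)


def compare_models(
    candidate: LabelVolume, gold: LabelVolume
) -> tuple[float, np.ndarray]:
    """3D IOU of binarized foregrounds plus the per-z-layer IOU profile.

    If the in-plane grids differ (e.g. different downscale factors) the
    candidate is resampled to the gold grid with nearest-neighbour
    interpolation; a z-extent mismatch is an error.
    """
    cv = candidate.voxels
    gv = gold.voxels
    if cv.shape[0] != gv.shape[0]:
        raise ValueError(
            f"incompatible z extents: {cv.shape[0]} vs {gv.shape[0]} layers"
        )
    if cv.shape != gv.shape:
        cv = resize(cv.astype(float), gv.shape, order=0,
                    anti_aliasing=False).astype(np.int32)
    iou = volume_iou(cv, gv)
    profile = np.array(
        [mask_iou(cv[z] > 0, gv[z] > 0) for z in range(gv.shape[0])]
    )
    return iou, profile


def automatic_masks(
    aligned: SliceStack,
    detector: DetectorConfig | None = None,
    cv_params: ChanVeseParams | None = None,
    ihc_params: IhcSegParams | None = None,
) -> list[np.ndarray]:
    """Automatic per-slice segmentation of an aligned stack.

    IHC routes straight to threshold segmentation; H&E runs detection
    first and feeds the boxes to the outside-in active contour.
    """
    if aligned.stain is Stain.IHC:
        return [segment_ihc(s.gray(), ihc_params) for s in aligned.slices]
    detections = run_detector(aligned, detector or DetectorConfig())
    return [
        segment_he(s.pixels, det.boxes, cv_params)
        for s, det in zip(aligned.slices, detections)
    ]


def run_matrix(
    stack: SliceStack,
    manual_masks: list[np.ndarray],
    manual_transforms: list["AffineTransform2D"],  # noqa: F821
    configs: tuple[PipelineConfig, ...] = STANDARD_CONFIGS,
    rec_params: ReconstructionParams | None = None,
    schedule: RegistrationSchedule | None = None,
    detector: DetectorConfig | None = None,
    hole_fix_options: tuple[bool, ...] = (True, False),
) -> pd.DataFrame:
    """Evaluate every requested configuration against the gold standard.

    ``manual_masks`` are per-slice ground-truth masks in the *acquired*
    (pre-registration) frame of each slice and ``manual_transforms`` map
    each slice back to the block reference frame; with phantom data both
    come from the generator's truth.  Returns one row per (config,
    hole_fix) with columns ``block_id, config, hole_fix, iou_3d,
    mean_layer_iou, sd_layer_iou``.
    """
    from dataclasses import replace

    rec_params = rec_params or ReconstructionParams()
    if len(manual_masks) != len(stack):
        raise ValueError("manual mask count must match the stack")
    if len(manual_transforms) != len(stack):
        raise ValueError("manual transform count must match the stack")

    # manual registration arm: truth masks resampled into the reference frame
    manual_reg_masks = [
        apply_transform(m.astype(float), t, fill=0.0, order=0) > 0.5
        for m, t in zip(manual_masks, manual_transforms)
    ]

    # lazy caches shared across configs
    _auto: dict[str, object] = {}

    def auto_registration():
        if "reg" not in _auto:
            _auto["reg"] = register_stack(stack, schedule)
        return _auto["reg"]

    def masks_for(cfg: PipelineConfig) -> list[np.ndarray]:
        key = (cfg.registration_source, cfg.segmentation_source)
        if key == ("manual", "manual"):
            return manual_reg_masks
        if key == ("manual", "automatic"):
            if "mras" not in _auto:
                aligned_slices = [
                    apply_transform(np.asarray(s.pixels, float), t,
                                    fill=None, order=1)
                    for s, t in zip(stack.slices, manual_transforms)
                ]
                aligned = SliceStack(
                    [type(s)(np.clip(a, 0, 1), s.pixel_size, s.slice_index)
                     for s, a in zip(stack.slices, aligned_slices)],
                    stain=stack.stain,
                    slice_thickness=stack.slice_thickness,
                    slice_spacing=stack.slice_spacing,
                    block_id=stack.block_id,
                )
                _auto["mras"] = automatic_masks(aligned, detector)
            return _auto["mras"]
        if key == ("automatic", "manual"):
            if "arms" not in _auto:
                _, transforms, _ = auto_registration()
                _auto["arms"] = [
                    apply_transform(m.astype(float), t, fill=0.0, order=0) > 0.5
                    for m, t in zip(manual_masks, transforms)
                ]
            return _auto["arms"]
        if "auto_masks" not in _auto:
            aligned, _, _ = auto_registration()
            _auto["auto_masks"] = automatic_masks(aligned, detector)
        return _auto["auto_masks"]

    rows = []
    for hf in hole_fix_options:
        params = replace(rec_params, hole_fix=hf)
        gold = reconstruct_block(
            manual_reg_masks, params, stack.pixel_size, stack.slice_spacing
        )
        for cfg in configs:
            masks = masks_for(cfg)
            if cfg.model_kind == "extrusion":
                model = extrude_first_slice(
                    masks, params, stack.pixel_size, stack.slice_spacing
                )
            else:
                model = reconstruct_block(
                    masks, params, stack.pixel_size, stack.slice_spacing
                )
            iou, profile = compare_models(model, gold)
            rows.append(
                {
                    "block_id": stack.block_id,
                    "config": cfg.name,
                    "hole_fix": hf,
                    "iou_3d": iou,
                    "mean_layer_iou": float(profile.mean()),
                    "sd_layer_iou": float(profile.std()),
                }
            )
    return pd.DataFrame(rows)
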