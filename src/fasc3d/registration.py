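"""Four-step multi-resolution affine alignment of consecutive sections.

Consecutive slices of a block are registered pairwise with an
intensity-based (mean-squares) metric and stochastic gradient descent,
in four passes of progressively richer transform families and finer
resolution:

1. translation only, at 25% resolution;
2. translation + rotation (rigid), at 50%;
3. translation + rotation + scale (similarity), at 75% for H&E or full
   resolution for IHC;
4. full affine (adds shear), at full resolution.

Each step is seeded with the previous step's result, so gross features are
aligned first on coarse images and details are fine-tuned later.  Per-slice
transforms to the block reference frame (slice 0) are obtained by chaining
the pairwise transforms; every slice is resampled exactly once through its
composed transform to avoid accumulating interpolation blur.

SimpleITK provides the optimizer and metric machinery; transforms are
exchanged with the rest of the package as plain 3x3 matrices acting on
full-resolution pixel coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from skimage import transform as sktransform
from skimage.metrics import structural_similarity

from .core import (
    AffineTransform2D,
    SliceImage,
    SliceStack,
    Stain,
    as_float,
    as_gray_float,
)
from .preprocess import PreprocessParams, preprocess_for_stain

__all__ = [
    "RegistrationSchedule",
    "RegistrationQuality",
    "default_schedule",
    "estimate_background",
    "apply_transform",
    "register_pair",
    "register_stack",
    "mse",
    "ssim",
]

_FAMILIES = ("translation", "rigid", "similarity", "affine")


@dataclass
class RegistrationSchedule:
    """Ordered (transform family, scale fraction) steps.

    Families must be nested (each step's family contains the previous) and
    scale fractions non-decreasing, so every step can be seeded exactly
    from its predecessor.
    """

    steps: list[tuple[str, float]]
    iterations: int = 100
    sampling_fraction: float = 0.2
    seed: int = 1  # metric-sampling seed; 0 would mean wall-clock (non-reproducible)
    # candidate initial angles (degrees) for the rigid step; the start whose
    # converged metric is lowest wins.  Rotations around +/-10 deg otherwise
    # risk a wrong-sign local minimum when fascicle layouts are near-symmetric.
    rigid_multistart_deg: tuple[float, ...] = (-10.0, -5.0, 0.0, 5.0, 10.0)

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("schedule needs at least one step")
        prev_rank, prev_scale = -1, 0.0
        for family, scale in self.steps:
            if family not in _FAMILIES:
                raise ValueError(f"unknown transform family: {family}")
            rank = _FAMILIES.index(family)
            if rank < prev_rank:
                raise ValueError("transform families must be nested")
            if not 0.0 < scale <= 1.0:
                raise ValueError("scale fractions must be in (0, 1]")
            if scale < prev_scale:
                raise ValueError("scale fractions must be non-decreasing")
            prev_rank, prev_scale = rank, scale


def default_schedule(stain: Stain | str = Stain.IHC) -> RegistrationSchedule:
    """The four-step schedule; step 3 runs at 75% for H&E, full for IHC."""
    stain = Stain(stain)
    step3 = 0.75 if stain is Stain.HE else 1.0
    return RegistrationSchedule(
        steps=[
            ("translation", 0.25),
            ("rigid", 0.5),
            ("similarity", step3),
            ("affine", 1.0),
        ]
    )


@dataclass
class RegistrationQuality:
    """Before/after alignment metrics for one slice pair.

    MSE is reported on the 0-255 intensity scale so deltas are comparable
    across images regardless of the internal float representation; SSIM is
    the mean structural similarity over the frame.
    """

    mse_before: float
    mse_after: float
    ssim_before: float
    ssim_after: float
    warning: bool = False


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared intensity error on the 0-255 scale."""
    a = as_gray_float(a)
    b = as_gray_float(b)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(((a - b) * 255.0) ** 2))


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity with standard constants, unit data range."""
    a = as_gray_float(a)
    b = as_gray_float(b)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    return float(structural_similarity(a, b, data_range=1.0))


def estimate_background(img: np.ndarray) -> float:
    """Median intensity of the image's border ring (width 2% of min dim).

    Robust estimate of the slide background used to fill regions exposed
    by resampling, so rotation does not introduce dark frames that would
    bias the next registration.
    """
    g = as_gray_float(img)
    h, w = g.shape
    width = max(1, int(round(0.02 * min(h, w))))
    ring = np.concatenate(
        [
            g[:width, :].ravel(),
            g[-width:, :].ravel(),
            g[width:-width, :width].ravel() if h > 2 * width else np.empty(0),
            g[width:-width, -width:].ravel() if h > 2 * width else np.empty(0),
        ]
    )
    return float(np.median(ring))


def apply_transform(
    img: np.ndarray,
    t: AffineTransform2D,
    fill: float | None = None,
    order: int = 1,
) -> np.ndarray:
    """Resample ``img`` so its content moves through ``t`` on the fixed frame.

    ``t`` maps source (moving) pixel coordinates to destination
    coordinates.  Interpolation is linear by default (``order=0`` for
    label/mask images); pixels falling outside the source domain are set
    to ``fill`` (default: estimated background), never silently to 0.
    """
    a = np.asarray(img, dtype=np.float64)
    if fill is None:
        fill = estimate_background(a)
    inv = np.linalg.inv(t.matrix)
    tform = sktransform.AffineTransform(matrix=inv)
    if a.ndim == 3:
        out = np.stack(
            [
                sktransform.warp(a[..., c], tform, order=order, cval=fill,
                                 mode="constant", preserve_range=True)
                for c in range(a.shape[2])
            ],
            axis=-1,
        )
    else:
        out = sktransform.warp(a, tform, order=order, cval=fill,
                               mode="constant", preserve_range=True)
    return out


# ---------------------------------------------------------------------------
# SimpleITK plumbing
# ---------------------------------------------------------------------------


def _to_sitk(arr: np.ndarray, scale: float) -> sitk.Image:
    """Downscale and wrap as a SimpleITK image in full-resolution coordinates.

    The physical spacing is set to 1/scale so optimizer parameters are in
    full-resolution pixel units at every pyramid level, letting one step's
    result seed the next without rescaling.
    """
    if scale < 1.0:
        small = sktransform.rescale(arr, scale, anti_aliasing=True, order=1)
    else:
        small = arr
    im = sitk.GetImageFromArray(np.ascontiguousarray(small, dtype=np.float32))
    im.SetSpacing((1.0 / scale, 1.0 / scale))
    # align pixel-center grids of the down-sampled and full-resolution images
    shift = 0.5 / scale - 0.5
    im.SetOrigin((shift, shift))
    return im


def _seed_transform(family: str, prev: sitk.Transform | None,
                    center: tuple[float, float]) -> sitk.Transform:
    """Build this step's transform, initialized from the previous step.

    Because the schedule's families are nested, the previous step's map is
    always exactly representable in the new family: its homogeneous matrix
    is decomposed about the new center.
    """
    m = _sitk_to_matrix(prev) if prev is not None else np.eye(3)
    c = np.asarray(center)

    def _translation_for(lin: np.ndarray) -> tuple[float, float]:
        return tuple(m[:2, 2] - c + lin @ c)

    if family == "translation":
        t = sitk.TranslationTransform(2)
        t.SetOffset(tuple(m[:2, 2]))
        return t
    if family == "rigid":
        t = sitk.Euler2DTransform()
        t.SetCenter(center)
        angle = float(np.arctan2(m[1, 0], m[0, 0]))
        t.SetAngle(angle)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        t.SetTranslation(_translation_for(rot))
        return t
    if family == "similarity":
        t = sitk.Similarity2DTransform()
        t.SetCenter(center)
        angle = float(np.arctan2(m[1, 0], m[0, 0]))
        scale = float(np.sqrt(max(abs(np.linalg.det(m[:2, :2])), 1e-12)))
        t.SetAngle(angle)
        t.SetScale(scale)
        lin = scale * np.array([[np.cos(angle), -np.sin(angle)],
                                [np.sin(angle), np.cos(angle)]])
        t.SetTranslation(_translation_for(lin))
        return t
    # full affine
    t = sitk.AffineTransform(2)
    t.SetCenter(center)
    t.SetMatrix(tuple(m[:2, :2].ravel()))
    t.SetTranslation(_translation_for(m[:2, :2]))
    return t


def _sitk_to_matrix(t: sitk.Transform) -> np.ndarray:
    """Homogeneous matrix of a SimpleITK 2D transform (maps fixed -> moving)."""
    if isinstance(t, sitk.TranslationTransform):
        a = np.eye(2)
        trans = np.asarray(t.GetOffset())
        center = np.zeros(2)
    else:
        a = np.asarray(t.GetMatrix()).reshape(2, 2)
        trans = np.asarray(t.GetTranslation())
        center = np.asarray(t.GetCenter())
    m = np.eye(3)
    m[:2, :2] = a
    m[:2, 2] = trans + center - a @ center
    return m


def register_pair(
    moving: np.ndarray,
    fixed: np.ndarray,
    stain: Stain | str = Stain.IHC,
    schedule: RegistrationSchedule | None = None,
    preprocessed: bool = True,
    pre_params: PreprocessParams | None = None,
) -> tuple[AffineTransform2D, RegistrationQuality]:
    """Register ``moving`` onto ``fixed`` with the four-step schedule.

    Inputs are expected to be preprocessed grayscale slices (pass
    ``preprocessed=False`` to run :func:`preprocess_for_stain` here).
    Returns the transform mapping moving-image content into the fixed
    frame, plus before/after MSE and SSIM computed on the full-resolution
    grayscale images.
    """
    stain = Stain(stain)
    schedule = schedule or default_schedule(stain)
    if not preprocessed:
        moving = preprocess_for_stain(moving, stain, pre_params)
        fixed = preprocess_for_stain(fixed, stain, pre_params)
    mov = as_gray_float(moving)
    fix = as_gray_float(fixed)
    if mov.shape != fix.shape:
        raise ValueError(f"image shape mismatch: {mov.shape} vs {fix.shape}")

    h, w = fix.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    def _make_reg() -> sitk.ImageRegistrationMethod:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(schedule.sampling_fraction,
                                        max(1, schedule.seed))
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsGradientDescent(
            learningRate=1.0,
            numberOfIterations=schedule.iterations,
            estimateLearningRate=reg.EachIteration,
            convergenceMinimumValue=1e-7,
            convergenceWindowSize=10,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        return reg

    def _full_metric(f_im, m_im, t) -> float:
        ev = sitk.ImageRegistrationMethod()
        ev.SetMetricAsMeanSquares()
        ev.SetInterpolator(sitk.sitkLinear)
        ev.SetInitialTransform(t, inPlace=False)
        return ev.MetricEvaluate(f_im, m_im)

    current: sitk.Transform | None = None
    warned = False
    rigid_started = False
    for family, scale in schedule.steps:
        f_im = _to_sitk(fix, scale)
        m_im = _to_sitk(mov, scale)
        seed_t = _seed_transform(family, current, center)
        if family == "rigid" and not rigid_started and schedule.rigid_multistart_deg:
            # multi-start over candidate angles; keep the converged result
            # with the lowest full-image metric
            rigid_started = True
            best: tuple[float, sitk.Transform] | None = None
            for deg in schedule.rigid_multistart_deg:
                cand = sitk.Euler2DTransform(seed_t)
                cand.SetAngle(cand.GetAngle() + float(np.deg2rad(deg)))
                reg = _make_reg()
                reg.SetInitialTransform(cand, inPlace=True)
                try:
                    reg.Execute(f_im, m_im)
                except RuntimeError:
                    continue
                value = _full_metric(f_im, m_im, cand)
                if best is None or value < best[0]:
                    best = (value, cand)
            if best is None:
                warnings.warn("all rigid multi-starts diverged")
                warned = True
                break
            current = best[1]
            continue
        reg = _make_reg()
        reg.SetInitialTransform(seed_t, inPlace=True)
        try:
            reg.Execute(f_im, m_im)
        except RuntimeError as err:  # optimizer divergence: keep best so far
            warnings.warn(f"registration step '{family}' failed: {err}")
            warned = True
            break
        current = seed_t

    if current is None:
        transform = AffineTransform2D.identity()
        warned = True
    else:
        # SimpleITK resampling transforms map fixed points to moving points;
        # the content of the moving image travels through the inverse.
        transform = AffineTransform2D(np.linalg.inv(_sitk_to_matrix(current)))

    fill = estimate_background(mov)
    aligned = apply_transform(mov, transform, fill=fill)
    quality = RegistrationQuality(
        mse_before=mse(mov, fix),
        mse_after=mse(aligned, fix),
        ssim_before=ssim(mov, fix),
        ssim_after=ssim(aligned, fix),
        warning=warned,
    )
    return transform, quality


def register_stack(
    stack: SliceStack,
    schedule: RegistrationSchedule | None = None,
    pre_params: PreprocessParams | None = None,
) -> tuple[SliceStack, list[AffineTransform2D], list[RegistrationQuality]]:
    """Align every slice of a block to the frame of slice 0.

    Pairwise transforms i -> i-1 are estimated on preprocessed images and
    chained into transforms to the reference frame; each original slice is
    then resampled once through its composed transform.  Returns the
    aligned stack, the per-slice transforms (identity for slice 0), and
    the n-1 pairwise quality records.
    """
    schedule = schedule or default_schedule(stack.stain)
    pre = [
        preprocess_for_stain(s.pixels, stack.stain, pre_params)
        for s in stack.slices
    ]
    to_ref: list[AffineTransform2D] = [AffineTransform2D.identity()]
    qualities: list[RegistrationQuality] = []
    for i in range(1, len(pre)):
        t_pair, q = register_pair(pre[i], pre[i - 1], stack.stain, schedule)
        qualities.append(q)
        to_ref.append(to_ref[i - 1] @ t_pair)

    aligned_slices = []
    for s, t in zip(stack.slices, to_ref):
        pixels = as_float(s.pixels)
        fill = estimate_background(as_gray_float(pixels))
        aligned = apply_transform(pixels, t, fill=fill)
        aligned_slices.append(
            SliceImage(np.clip(aligned, 0.0, 1.0), s.pixel_size, s.slice_index)
        )
    aligned_stack = SliceStack(
        aligned_slices,
        stain=stack.stain,
        slice_thickness=stack.slice_thickness,
        slice_spacing=stack.slice_spacing,
        block_id=stack.block_id,
    )
    return aligned_stack, to_ref, qualities
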