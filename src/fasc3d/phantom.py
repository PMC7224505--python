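"""Ground-truthed synthetic nerve blocks for exercising the pipeline.

A phantom block emulates the geometry of serial nerve cross-sections:
several roughly elliptical fascicles whose centers wander smoothly from
slice to slice, optional branch events where one fascicle splits in two,
dark-on-light high-contrast rendering (IHC-like) or low-contrast textured
RGB rendering (HE-like), per-slice rigid/affine misalignment with the
true transforms recorded, and slice-level fascicle dropout emulating
missed detections.  Every generated quantity — per-slice masks and boxes
in both the original and the misaligned frame, per-slice transforms, and
a dense labeled truth volume — is available as ground truth, so the
registration, detection, segmentation and reconstruction stages can all
be scored without any manual annotation.

The appearance model is deliberately simple (two intensity levels plus
noise and, for HE, a smooth texture): the pipeline's logic, not
photorealism, is what these phantoms are meant to test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .core import (
    AffineTransform2D,
    BoundingBox,
    SliceImage,
    SliceStack,
    Stain,
)
from .registration import apply_transform

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "truth_boxes",
    "truth_masks",
]

# appearance constants: fascicle / background intensity per stain model
_IHC_FG, _IHC_BG = 0.2, 0.9
_HE_FG, _HE_BG = 0.55, 0.7
_HE_TEXTURE_AMP = 0.04


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic nerve block.

    ``misalignment`` is (max |translation| px, max |rotation| deg,
    max |shear| deg), drawn uniformly per slice; slice 0 is the reference
    and is never perturbed.  ``branch_events`` lists (slice_index,
    fascicle_id) splits; ``dropout`` lists (slice_index, fascicle_id)
    omissions from the rendering and per-slice ground truth.  All
    randomness flows from ``seed``.
    """

    n_slices: int = 12
    image_size: int = 512
    n_fascicles: int = 6
    fascicle_radii: tuple[float, float] = (10.0, 28.0)
    centerline_wander: float = 2.0
    branch_events: list[tuple[int, int]] = field(default_factory=list)
    stain_model: str = "IHC_like"
    misalignment: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dropout: list[tuple[int, int]] = field(default_factory=list)
    noise_sd: float = 0.02
    max_aspect: float = 1.4
    slice_thickness: float = 5.0
    slice_spacing: float = 250.0
    pixel_size: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 2:
            raise ValueError("n_slices must be >= 2")
        rmin, rmax = self.fascicle_radii
        if rmin < 7.0:
            raise ValueError("minimum fascicle radius is 7 px (14 px diameter)")
        if rmax < rmin:
            raise ValueError("fascicle_radii must be (min, max)")
        if self.stain_model not in ("IHC_like", "HE_like"):
            raise ValueError("stain_model must be 'IHC_like' or 'HE_like'")
        for s, _ in self.branch_events:
            if not 1 <= s <= self.n_slices - 1:
                raise ValueError(f"branch slice {s} outside [1, n_slices-1]")
        if self.max_aspect < 1.0:
            raise ValueError("max_aspect must be >= 1")

    @property
    def stain(self) -> Stain:
        return Stain.HE if self.stain_model == "HE_like" else Stain.IHC


class _Tube:
    """One fascicle's elliptical cross-section along its z extent."""

    def __init__(self, label: int, idx: np.ndarray, centers: np.ndarray,
                 axes: np.ndarray, angles: np.ndarray):
        self.label = label
        self.idx = idx  # integer slice indices where the tube exists
        self.centers = centers
        self.axes = axes
        self.angles = angles

    def exists_at(self, z: float) -> bool:
        return self.idx[0] <= z <= self.idx[-1]

    def params_at(self, z: float) -> tuple[np.ndarray, np.ndarray, float]:
        c = np.array([np.interp(z, self.idx, self.centers[:, k]) for k in (0, 1)])
        a = np.array([np.interp(z, self.idx, self.axes[:, k]) for k in (0, 1)])
        th = float(np.interp(z, self.idx, self.angles))
        return c, a, th


def _ellipse_mask(shape: tuple[int, int], center: np.ndarray,
                  axes: np.ndarray, angle: float,
                  scale: float = 1.0) -> np.ndarray:
    """Rasterize a rotated filled ellipse given in full-resolution coords.

    ``scale`` < 1 evaluates the same analytic shape on a coarser grid
    whose pixel centers follow the skimage resize convention.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    if scale != 1.0:
        xx = (xx + 0.5) / scale - 0.5
        yy = (yy + 0.5) / scale - 0.5
    dx = xx - center[0]
    dy = yy - center[1]
    ct, st = np.cos(angle), np.sin(angle)
    u = (dx * ct + dy * st) / axes[0]
    v = (-dx * st + dy * ct) / axes[1]
    return u * u + v * v <= 1.0


@dataclass
class PhantomTruth:
    """Complete ground truth of one generated block.

    ``transforms[i]`` maps slice ``i``'s misaligned content back into the
    original (unperturbed) frame — the transform a perfect registration
    would recover, up to the frame of slice 0.  Dropout entries are
    treated as observation failures: they are absent from the per-slice
    masks and boxes but present in the anatomical truth volume.
    """

    spec: PhantomSpec
    masks_original: list[np.ndarray]
    masks_misaligned: list[np.ndarray]
    labels_original: list[np.ndarray]
    labels_misaligned: list[np.ndarray]
    transforms: list[AffineTransform2D]
    tubes: list[_Tube]

    def boxes(self, frame: str = "original") -> list[list[BoundingBox]]:
        labels = self._labels(frame)
        out = []
        for lab in labels:
            boxes = []
            for k in np.unique(lab[lab > 0]):
                ys, xs = np.nonzero(lab == k)
                boxes.append(
                    BoundingBox(int(xs.min()), int(ys.min()),
                                int(xs.max()) - int(xs.min()) + 1,
                                int(ys.max()) - int(ys.min()) + 1)
                )
            out.append(boxes)
        return out

    def _labels(self, frame: str) -> list[np.ndarray]:
        if frame == "original":
            return self.labels_original
        if frame == "misaligned":
            return self.labels_misaligned
        raise ValueError(f"unknown frame: {frame}")

    def masks(self, frame: str = "original") -> list[np.ndarray]:
        if frame == "original":
            return self.masks_original
        if frame == "misaligned":
            return self.masks_misaligned
        raise ValueError(f"unknown frame: {frame}")

    def volume(self, n_intermediate: int = 4, downscale: float = 1.0):
        """Dense labeled truth volume on the reconstruction output grid.

        Renders the analytic tubes at every interpolated z position (in
        the original frame), so comparisons against
        :func:`~fasc3d.reconstruction.reconstruct_block` need no
        resampling.
        """
        from .core import LabelVolume

        spec = self.spec
        size = spec.image_size
        shape = (max(1, round(size * downscale)),) * 2
        n_layers = spec.n_slices + (spec.n_slices - 1) * n_intermediate
        vol = np.zeros((n_layers,) + shape, dtype=np.int32)
        for layer in range(n_layers):
            z = layer / (n_intermediate + 1)
            for tube in self.tubes:
                if not tube.exists_at(z):
                    continue
                c, a, th = tube.params_at(z)
                m = _ellipse_mask(shape, c, a, th, scale=downscale)
                vol[layer][m] = tube.label + 1
        in_plane = spec.pixel_size / downscale
        voxel = (in_plane, in_plane, spec.slice_spacing / (n_intermediate + 1))
        return LabelVolume(vol, voxel)


def truth_boxes(truth: PhantomTruth, frame: str = "original"):
    """Per-slice detection ground truth (tight boxes of mask components)."""
    return truth.boxes(frame)


def truth_masks(truth: PhantomTruth, frame: str = "original"):
    """Per-slice segmentation ground truth in the requested frame."""
    return truth.masks(frame)


def _build_tubes(spec: PhantomSpec, rng: np.random.Generator) -> list[_Tube]:
    n = spec.n_slices
    size = spec.image_size
    rmin, rmax = spec.fascicle_radii
    margin = 15.0

    tubes: list[_Tube] = []
    placed: list[tuple[np.ndarray, float]] = []
    for fid in range(spec.n_fascicles):
        rx = rng.uniform(rmin, rmax)
        aspect = rng.uniform(1.0, spec.max_aspect)
        ry = max(rx / aspect, rmin)
        r_eff = max(rx, ry)
        for _ in range(2000):
            c = rng.uniform(r_eff + margin, size - r_eff - margin, size=2)
            if all(np.linalg.norm(c - pc) > r_eff + pr + margin
                   for pc, pr in placed):
                break
        else:
            break  # no room left; fewer fascicles than requested
        placed.append((c, r_eff))
        steps = rng.uniform(-spec.centerline_wander, spec.centerline_wander,
                            size=(n, 2))
        steps[0] = 0.0
        centers = c + np.cumsum(steps, axis=0)
        # all along-z shape variation scales with the wander amplitude so
        # a zero-wander spec yields perfectly prismatic tubes
        drift = 1.0 + np.clip(
            np.cumsum(rng.normal(0, 0.005 * spec.centerline_wander, n)), -0.1, 0.1
        )
        axes = np.column_stack([rx * drift, ry * drift])
        angles = rng.uniform(0, np.pi) + np.cumsum(
            rng.normal(0, 0.01 * spec.centerline_wander, n)
        )
        tubes.append(_Tube(fid, np.arange(n), centers, axes, angles))

    next_label = len(tubes)
    for s, parent_id in spec.branch_events:
        if parent_id >= len(tubes):
            raise ValueError(f"branch parent {parent_id} does not exist")
        parent = tubes[parent_id]
        if not (parent.idx[0] < s <= parent.idx[-1]):
            raise ValueError(f"branch slice {s} outside parent extent")
        cut = int(np.searchsorted(parent.idx, s))
        start = s - 1
        p_at = int(np.searchsorted(parent.idx, start))
        p_center = parent.centers[p_at]
        p_axes = parent.axes[p_at]
        p_angle = parent.angles[p_at]
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        sep = 0.9 * max(p_axes)
        for sign in (+1.0, -1.0):
            idx = np.arange(start, n)
            rel = (idx - start).astype(float)
            wander = np.cumsum(
                rng.uniform(-spec.centerline_wander, spec.centerline_wander,
                            size=(len(idx), 2)), axis=0)
            wander[0] = 0.0
            centers = p_center + sign * np.outer(rel, direction) * sep + wander
            axes = np.tile(p_axes * 0.72, (len(idx), 1))
            angles = np.full(len(idx), p_angle)
            tubes.append(_Tube(next_label, idx, centers, axes, angles))
            next_label += 1
        # parent ends where the children take over
        parent.idx = parent.idx[:cut]
        parent.centers = parent.centers[:cut]
        parent.axes = parent.axes[:cut]
        parent.angles = parent.angles[:cut]
    return tubes


def _render_slice(spec: PhantomSpec, labels: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Clean (noise-free) rendering of one slice from its label image."""
    size = spec.image_size
    fg = labels > 0
    if spec.stain_model == "IHC_like":
        img = np.full((size, size), _IHC_BG)
        img[fg] = _IHC_FG
        return img
    base = np.full((size, size), _HE_BG)
    base[fg] = _HE_FG
    texture = ndi.gaussian_filter(rng.normal(0, 1.0, (size, size)), 4.0)
    texture *= _HE_TEXTURE_AMP / max(texture.std(), 1e-12)
    gray = np.clip(base + texture, 0.0, 1.0)
    # eosin-pink tint; luma stays close to the gray pattern
    rgb = np.stack([
        np.clip(gray * 1.08, 0, 1),
        np.clip(gray * 0.88, 0, 1),
        np.clip(gray * 1.02, 0, 1),
    ], axis=-1)
    return rgb


def generate_phantom(spec: PhantomSpec) -> tuple[SliceStack, PhantomTruth]:
    """Generate one synthetic block and its full ground truth.

    Deterministic for a fixed spec (bit-identical across runs).  Returns
    the stack of rendered, misaligned, noisy slice images plus the
    :class:`PhantomTruth` with masks, boxes, transforms and the analytic
    truth volume generator.
    """
    rng = np.random.default_rng(spec.seed)
    tubes = _build_tubes(spec, rng)
    size = spec.image_size
    n = spec.n_slices
    dropped = set(spec.dropout)

    labels_original: list[np.ndarray] = []
    for i in range(n):
        lab = np.zeros((size, size), dtype=np.int32)
        for tube in tubes:
            if not tube.exists_at(i) or (i, tube.label) in dropped:
                continue
            c, a, th = tube.params_at(i)
            lab[_ellipse_mask((size, size), c, a, th)] = tube.label + 1
        labels_original.append(lab)

    clean_images = [_render_slice(spec, lab, rng) for lab in labels_original]

    max_t, max_rot, max_shear = spec.misalignment
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    transforms: list[AffineTransform2D] = [AffineTransform2D.identity()]
    for _ in range(1, n):
        t = rng.uniform(-max_t, max_t, size=2)
        rot = rng.uniform(-max_rot, max_rot)
        shear = rng.uniform(-max_shear, max_shear)
        mis = AffineTransform2D.from_params(tuple(t), rot, 1.0, shear, center)
        transforms.append(mis.inverse())  # recorded: misaligned -> original

    labels_misaligned: list[np.ndarray] = []
    images: list[SliceImage] = []
    bg = _IHC_BG if spec.stain_model == "IHC_like" else _HE_BG
    for i in range(n):
        mis = transforms[i].inverse()  # original -> misaligned frame
        if np.allclose(mis.matrix, np.eye(3)):
            lab_m = labels_original[i].copy()
            img_m = np.array(clean_images[i], copy=True)
        else:
            lab_m = apply_transform(
                labels_original[i].astype(float), mis, fill=0.0, order=0
            ).astype(np.int32)
            img_m = apply_transform(clean_images[i], mis, fill=bg)
        if spec.noise_sd > 0:
            img_m = img_m + rng.normal(0, spec.noise_sd, img_m.shape)
        img_m = np.clip(img_m, 0.0, 1.0)
        labels_misaligned.append(lab_m)
        images.append(SliceImage(img_m, spec.pixel_size, i))

    stack = SliceStack(
        images,
        stain=spec.stain,
        slice_thickness=spec.slice_thickness,
        slice_spacing=spec.slice_spacing,
        block_id=f"phantom-{spec.seed}",
    )
    truth = PhantomTruth(
        spec=spec,
        masks_original=[lab > 0 for lab in labels_original],
        masks_misaligned=[lab > 0 for lab in labels_misaligned],
        labels_original=labels_original,
        labels_misaligned=labels_misaligned,
        transforms=transforms,
        tubes=tubes,
    )
    return stack, truth
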