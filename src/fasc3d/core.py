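"""Shared domain types and overlap metrics for the fascicle-reconstruction pipeline.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based and row-major; ``(x, y)`` denotes
  (column, row).  Bounding boxes are half-open: a box ``(x0, y0, w, h)``
  covers the pixels ``[x0, x0+w) x [y0, y0+h)``.
* Grayscale images are ``float`` arrays with values in ``[0, 1]``; RGB
  images are ``(H, W, 3)`` arrays (uint8 or float).
* Binary masks are boolean arrays aligned to their slice frame, with
  ``True`` marking fascicle tissue.
* Affine transforms act on homogeneous ``(x, y, 1)`` column vectors via a
  3x3 matrix whose last row is ``(0, 0, 1)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Stain",
    "SliceImage",
    "SliceStack",
    "AffineTransform2D",
    "BoundingBox",
    "LabelVolume",
    "box_iou",
    "mask_iou",
    "volume_iou",
    "as_gray_float",
    "as_float",
]


class Stain(str, enum.Enum):
    """Histological stain of a block.

    ``HE`` (hematoxylin & eosin) gives low fascicle/background contrast and
    needs heavy preprocessing plus a detection step; ``IHC``
    (anti-neurofilament immunohistochemistry) stains fascicles dark on a
    light ground and can be thresholded directly.
    """

    HE = "HE"
    IHC = "IHC"


def as_float(pixels: np.ndarray) -> np.ndarray:
    """Return ``pixels`` as float64 in [0, 1], preserving any channel axis."""
    a = np.asarray(pixels)
    if np.issubdtype(a.dtype, np.integer):
        a = a.astype(np.float64) / np.iinfo(a.dtype).max
    else:
        a = a.astype(np.float64, copy=False)
    return np.clip(a, 0.0, 1.0)


def as_gray_float(pixels: np.ndarray) -> np.ndarray:
    """Return ``pixels`` as a float64 grayscale array in [0, 1].

    RGB input is converted with the ITU-R BT.601 luma weights; integer
    input is rescaled from its dtype range.
    """
    a = np.asarray(pixels)
    if np.issubdtype(a.dtype, np.integer):
        a = a.astype(np.float64) / np.iinfo(a.dtype).max
    else:
        a = a.astype(np.float64, copy=False)
    if a.ndim == 3:
        a = a[..., :3] @ np.array([0.299, 0.587, 0.114])
    return np.clip(a, 0.0, 1.0)


@dataclass
class SliceImage:
    """One histological cross-section and its physical scale.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` grayscale float in [0, 1] or ``(H, W, 3)`` RGB.
    pixel_size : float
        In-plane sampling, micrometres per pixel.
    slice_index : int
        Position of the slice within its block (0-based).
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2D grayscale or (H, W, 3) RGB")
        if self.height == 0 or self.width == 0:
            raise ValueError("image must be non-empty")
        if self.pixels.ndim == 2 and np.issubdtype(self.pixels.dtype, np.floating):
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError("grayscale values must lie in [0, 1]")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def gray(self) -> np.ndarray:
        return as_gray_float(self.pixels)


@dataclass
class SliceStack:
    """An ordered block of serial sections sharing stain and spacing.

    ``slice_thickness`` is the physical section thickness (default 5 um)
    and ``slice_spacing`` the interval between consecutive sections
    (default 250 um), so most of the tissue between sections is unobserved
    and must be interpolated during reconstruction.
    """

    slices: list[SliceImage]
    stain: Stain = Stain.IHC
    slice_thickness: float = 5.0
    slice_spacing: float = 250.0
    block_id: str = "block"

    def __post_init__(self) -> None:
        if len(self.slices) < 2:
            raise ValueError("a stack needs at least 2 slices")
        if not (self.slice_spacing > self.slice_thickness > 0):
            raise ValueError("require spacing > thickness > 0")
        self.stain = Stain(self.stain)
        indices = [s.slice_index for s in self.slices]
        if len(set(indices)) != len(indices):
            raise ValueError("slice_index values must be unique within a stack")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def pixel_size(self) -> float:
        return self.slices[0].pixel_size


@dataclass
class AffineTransform2D:
    """2D affine map on (x, y) pixel coordinates in homogeneous form.

    ``matrix`` maps source points to destination points:
    ``(x', y', 1)^T = matrix @ (x, y, 1)^T``.  The fixed point used when
    building rotation/scale/shear components defaults to the image center.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if not np.allclose(self.matrix[2], (0.0, 0.0, 1.0)):
            raise ValueError("last row must be (0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:2, :2])) < 1e-12:
            raise ValueError("transform must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(3))

    @classmethod
    def from_params(
        cls,
        translation: tuple[float, float] = (0.0, 0.0),
        rotation_deg: float = 0.0,
        scale: float | tuple[float, float] = 1.0,
        shear_deg: float = 0.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Compose translation * (rotation/scale/shear about ``center``)."""
        sx, sy = (scale, scale) if np.isscalar(scale) else scale
        th = np.deg2rad(rotation_deg)
        sh = np.tan(np.deg2rad(shear_deg))
        lin = np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        ) @ np.array([[sx, sx * sh], [0.0, sy]])
        cx, cy = center
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = np.array([cx, cy]) - lin @ np.array([cx, cy])
        m[0, 2] += translation[0]
        m[1, 2] += translation[1]
        return cls(m)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return the map equivalent to applying ``other`` first, then self."""
        return AffineTransform2D(self.matrix @ other.matrix)

    def __matmul__(self, other: "AffineTransform2D") -> "AffineTransform2D":
        return self.compose(other)

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(np.linalg.inv(self.matrix))

    def apply_points(self, xy: np.ndarray) -> np.ndarray:
        """Map an ``(N, 2)`` array of (x, y) points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        h = np.hstack([xy, np.ones((len(xy), 1))])
        return (self.matrix @ h.T).T[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2].copy()

    @property
    def rotation_deg(self) -> float:
        """Rotation angle extracted from the linear part (ignores shear)."""
        return float(np.rad2deg(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    @property
    def scale(self) -> float:
        """Mean isotropic scale, sqrt(|det|) of the linear part."""
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:2, :2]))))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open pixel box ``[x0, x0+w) x [y0, y0+h)``."""

    x0: float
    y0: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extents must be positive")

    @property
    def x1(self) -> float:
        return self.x0 + self.w

    @property
    def y1(self) -> float:
        return self.y0 + self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + self.w / 2.0, self.y0 + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def clip(self, width: int, height: int) -> "BoundingBox | None":
        """Intersect with the image frame; None if nothing remains."""
        x0, y0 = max(self.x0, 0), max(self.y0, 0)
        x1, y1 = min(self.x1, width), min(self.y1, height)
        if x1 <= x0 or y1 <= y0:
            return None
        return BoundingBox(x0, y0, x1 - x0, y1 - y0)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.w, self.h)


@dataclass
class LabelVolume:
    """Labeled 3D voxel raster: 0 = background, k >= 1 = fascicle k.

    ``voxels`` is indexed ``(z, y, x)``; ``voxel_size`` is ``(x, y, z)``
    in micrometres.  Peripheral-nerve stacks are strongly anisotropic
    (inter-section spacing far exceeds in-plane sampling), so the spacing
    is carried explicitly rather than assumed isotropic.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (z, y, x)")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must be an integer raster")
        if self.voxels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.voxels.max())

    def foreground(self) -> np.ndarray:
        return self.voxels > 0


# ---------------------------------------------------------------------------
# Overlap metrics
# ---------------------------------------------------------------------------


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open boxes (area ratio in [0, 1])."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Foreground IOU of two binary masks of identical shape.

    Two empty masks count as perfect agreement (1.0); empty versus
    non-empty is 0.0.  This keeps per-slice aggregates NaN-free.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def volume_iou(a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray) -> float:
    """IOU of the binarized foregrounds of two label volumes on one grid.

    Model-level comparison: any positive label counts as fascicle tissue,
    so the score is insensitive to how identities were numbered.
    """
    av = a.voxels if isinstance(a, LabelVolume) else np.asarray(a)
    bv = b.voxels if isinstance(b, LabelVolume) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError(f"volume grid mismatch: {av.shape} vs {bv.shape}")
    return mask_iou(av > 0, bv > 0)
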