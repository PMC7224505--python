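"""Reading and writing the pipeline's on-disk artifacts.

Images and masks travel as (multi-page) TIFF, label volumes as NRRD with
the voxel size in the header (or multi-page TIFF without it), boxes and
transforms as JSON carrying an explicit coordinate-convention field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .core import AffineTransform2D, LabelVolume, SliceImage, SliceStack, Stain, as_float

__all__ = [
    "load_stack",
    "save_stack",
    "load_masks",
    "save_masks",
    "save_volume",
    "load_volume",
    "save_transforms_json",
    "load_transforms_json",
]

COORD_CONVENTION = "0-based, row-major, (x, y) = (column, row); matrix maps (x, y, 1) column vectors"


def load_stack(
    path: str | Path,
    stain: Stain | str = Stain.IHC,
    pixel_size: float = 1.0,
    slice_thickness: float = 5.0,
    slice_spacing: float = 250.0,
    block_id: str | None = None,
) -> SliceStack:
    """Read a block from a multi-page TIFF (one page per slice, in order)."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        raise ValueError("a stack needs at least 2 pages")
    slices = [
        SliceImage(as_float(page), pixel_size, i) for i, page in enumerate(pages)
    ]
    return SliceStack(
        slices,
        stain=Stain(stain),
        slice_thickness=slice_thickness,
        slice_spacing=slice_spacing,
        block_id=block_id or path.stem,
    )


def save_stack(path: str | Path, stack: SliceStack) -> None:
    """Write a block as a multi-page float32 TIFF."""
    pages = np.asarray(
        [np.asarray(s.pixels, dtype=np.float32) for s in stack.slices]
    )
    tifffile.imwrite(path, pages)


def save_masks(path: str | Path, masks: list[np.ndarray] | np.ndarray) -> None:
    """Write binary masks as a multi-page bilevel (uint8 0/255) TIFF."""
    pages = np.asarray([np.asarray(m, bool) for m in masks], dtype=np.uint8) * 255
    tifffile.imwrite(path, pages)


def load_masks(path: str | Path) -> list[np.ndarray]:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return [p > 0 for p in pages]


def save_volume(path: str | Path, volume: LabelVolume) -> None:
    """Write a label volume; NRRD keeps the voxel size in its header."""
    path = Path(path)
    if path.suffix.lower() in (".nrrd", ".nhdr"):
        im = sitk.GetImageFromArray(volume.voxels.astype(np.int32))
        im.SetSpacing(tuple(float(v) for v in volume.voxel_size))
        sitk.WriteImage(im, str(path))
    else:
        tifffile.imwrite(path, volume.voxels.astype(np.int32))


def load_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    if path.suffix.lower() in (".nrrd", ".nhdr"):
        im = sitk.ReadImage(str(path))
        voxels = sitk.GetArrayFromImage(im).astype(np.int32)
        return LabelVolume(voxels, tuple(im.GetSpacing()))
    return LabelVolume(tifffile.imread(path).astype(np.int32))


def save_transforms_json(
    path: str | Path, transforms: list[AffineTransform2D]
) -> None:
    payload = {
        "convention": COORD_CONVENTION,
        "transforms": [t.matrix.tolist() for t in transforms],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_transforms_json(path: str | Path) -> list[AffineTransform2D]:
    try:
        payload = json.loads(Path(path).read_text())
        return [AffineTransform2D(np.asarray(m)) for m in payload["transforms"]]
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as err:
        raise ValueError(f"malformed transforms JSON at {path}: {err}") from err
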