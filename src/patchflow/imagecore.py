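"""Core image containers and file I/O.

The package works on two families of images: 3D radiology-style volumes
stored as NIfTI (with physical voxel spacing in mm) and flat 2D
histology-style images stored as PNG or single-page TIFF (unitless spacing
of 1.0 per axis).  Everything downstream consumes :class:`GridImage`
(real-valued, channel-first) and :class:`LabelMap` (integer, no channel
axis) so the rest of the pipeline never touches file formats directly.

Conventions
-----------
* The channel axis is explicit and first; a 2D RGB file maps to three
  channels in R, G, B order.
* Coordinates are 0-based; windows are half-open ``[start, start + size)``.
* Intensities are promoted to float64 on read; label maps stay integer.
* NIfTI axis order is taken as stored — no reorientation is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np
import tifffile
from PIL import Image as PILImage

from .errors import FormatError

__all__ = [
    "GridImage",
    "LabelMap",
    "ProbabilityMap",
    "read_image",
    "read_label",
    "write_image",
    "downsample",
]

_NIFTI_EXTS = (".nii", ".nii.gz")
_FLAT_EXTS = (".png", ".tif", ".tiff")


def _extension(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


@dataclass
class GridImage:
    """An n-dimensional intensity grid with physical spacing.

    Parameters
    ----------
    data
        Array indexed ``[channel, *spatial]``; promoted to float64.
    spacing
        Physical size of one pixel/voxel per spatial axis (mm for
        radiology volumes, 1.0 for unitless 2D images).
    origin
        Physical position of index ``(0, ..., 0)``; defaults to zeros.
    """

    data: np.ndarray
    spacing: tuple
    origin: tuple = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim < 3:
            raise ValueError(
                "GridImage data must be [channel, *spatial] with 2 or 3 "
                f"spatial axes, got array of ndim {self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        n_spatial = self.data.ndim - 1
        if n_spatial not in (2, 3):
            raise ValueError(f"only 2D/3D images supported, got {n_spatial} spatial axes")
        if len(self.spacing) != n_spatial:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for {n_spatial} spatial axes"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.origin is None:
            self.origin = (0.0,) * n_spatial
        else:
            self.origin = tuple(float(o) for o in self.origin)
        if len(self.origin) != n_spatial:
            raise ValueError("origin length must match the number of spatial axes")

    @property
    def ndim_spatial(self) -> int:
        return self.data.ndim - 1

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[1:]

    def channel(self, c: int) -> "GridImage":
        """Single-channel view as a new GridImage."""
        return GridImage(self.data[c : c + 1], self.spacing, self.origin)

    def with_data(self, data: np.ndarray) -> "GridImage":
        return GridImage(data, self.spacing, self.origin)


@dataclass
class LabelMap:
    """Integer-valued grid aligned to a GridImage's spatial shape.

    Values are non-negative integers; 0 denotes background.
    """

    data: np.ndarray
    spacing: tuple = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("LabelMap values must be integers")
            arr = np.round(arr).astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if arr.min(initial=0) < 0:
            raise ValueError("LabelMap values must be non-negative")
        self.data = arr
        if self.spacing is None:
            self.spacing = (1.0,) * arr.ndim
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != arr.ndim:
            raise ValueError("spacing length must match label-map dimensionality")

    @property
    def labels(self) -> set:
        return set(int(v) for v in np.unique(self.data))

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape


@dataclass
class ProbabilityMap:
    """Per-class probability grid indexed ``[class, *spatial]``.

    Values lie in [0, 1]; on covered pixels the per-pixel class values sum
    to 1 (within 1e-6).  Uncovered pixels carry probability 1 for the
    background class by convention.
    """

    data: np.ndarray
    classes: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.classes = tuple(int(c) for c in self.classes)
        if self.data.shape[0] != len(self.classes):
            raise ValueError("first axis must match the number of classes")
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")

    def argmax_labels(self, spacing=None) -> LabelMap:
        idx = np.argmax(self.data, axis=0)
        lut = np.asarray(self.classes, dtype=np.int64)
        return LabelMap(lut[idx], spacing=spacing)


def read_image(path) -> GridImage:
    """Read a NIfTI volume or flat 2D image into a GridImage.

    NIfTI yields 3 spatial axes with spacing from the header; PNG/TIFF
    yield 2 spatial axes with spacing (1.0, 1.0).  RGB files become three
    channels, grayscale one.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    ext = _extension(path)
    try:
        if ext in _NIFTI_EXTS:
            img = nib.load(str(path))
            arr = np.asanyarray(img.dataobj).astype(np.float64)
            if arr.ndim != 3:
                raise FormatError(f"expected a 3D NIfTI volume, got ndim {arr.ndim}: {path}")
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            origin = tuple(float(v) for v in img.affine[:3, 3])
            return GridImage(arr[None], spacing, origin)
        if ext == ".png":
            arr = np.asarray(PILImage.open(path))
        elif ext in (".tif", ".tiff"):
            arr = np.asarray(tifffile.imread(str(path)))
        else:
            raise FormatError(f"unsupported image extension {ext!r}: {path}")
    except FormatError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise FormatError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        data = arr[None]
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4):
        data = np.moveaxis(arr[..., :3], -1, 0)  # drop alpha if present
    else:
        raise FormatError(f"unsupported 2D image layout {arr.shape}: {path}")
    return GridImage(data, (1.0, 1.0))


def read_label(path) -> LabelMap:
    """Read a stored label mask; single-channel, values cast to integers."""
    img = read_image(path)
    if img.n_channels != 1:
        raise FormatError(f"label mask must be single-channel: {path}")
    return LabelMap(img.data[0], spacing=img.spacing)


def write_image(image: Union[GridImage, LabelMap], path) -> None:
    """Write a GridImage or LabelMap to NIfTI (3D) or PNG/TIFF (2D).

    The file is readable back by :func:`read_image`; label maps are stored
    with an integer dtype.
    """
    path = Path(path)
    ext = _extension(path)
    is_label = isinstance(image, LabelMap)
    if is_label:
        arr = image.data
        spacing = image.spacing
        origin = (0.0,) * arr.ndim
        ndim_spatial = arr.ndim
    else:
        arr = image.data
        spacing = image.spacing
        origin = image.origin
        ndim_spatial = image.ndim_spatial
    try:
        if ext in _NIFTI_EXTS:
            if ndim_spatial != 3:
                raise FormatError(f"NIfTI output requires a 3D image: {path}")
            vol = arr if is_label else arr[0] if arr.shape[0] == 1 else None
            if vol is None:
                raise FormatError(f"multi-channel 3D write is not supported: {path}")
            affine = np.diag(list(spacing) + [1.0])
            affine[:3, 3] = origin
            if is_label:
                vol = vol.astype(np.int16)
            nib.save(nib.Nifti1Image(vol, affine), str(path))
            return
        if ext not in _FLAT_EXTS:
            raise FormatError(f"unsupported image extension {ext!r}: {path}")
        if ndim_spatial != 2:
            raise FormatError(f"PNG/TIFF output requires a 2D image: {path}")
        if is_label:
            plane = arr
        elif arr.shape[0] == 1:
            plane = arr[0]
        elif arr.shape[0] == 3:
            plane = np.moveaxis(arr, 0, -1)
        else:
            raise FormatError(f"2D write supports 1 or 3 channels, got {arr.shape[0]}")
        if ext == ".png":
            out = plane if is_label else np.round(plane)
            if out.min() < 0 or out.max() > 255:
                raise FormatError(
                    f"PNG stores 8-bit values; data in [{out.min()}, {out.max()}] "
                    f"must be rescaled first: {path}"
                )
            PILImage.fromarray(out.astype(np.uint8)).save(path)
        else:
            out = plane.astype(np.int32) if is_label else plane
            tifffile.imwrite(str(path), out)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not write image {path}: {exc}") from exc


def downsample(image: GridImage, factor: int) -> GridImage:
    """Block-mean downsampling by an integer factor.

    Each spatial axis length becomes ``ceil(len / factor)``; every output
    value is the mean of its (possibly partial, at the far edge) block, and
    spacing is multiplied by the factor.  Simulates buffering a coarser
    magnification level of a slide.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    if factor == 1:
        return GridImage(image.data.copy(), image.spacing, image.origin)
    sums = image.data
    counts = np.ones((), dtype=np.float64)
    for ax in range(1, image.data.ndim):
        n = sums.shape[ax]
        idx = np.arange(0, n, factor)
        sums = np.add.reduceat(sums, idx, axis=ax)
        block_len = np.minimum(factor, n - idx).astype(np.float64)
        shape = [1] * image.data.ndim
        shape[ax] = len(idx)
        counts = counts * block_len.reshape(shape)
    spacing = tuple(s * factor for s in image.spacing)
    return GridImage(sums / counts, spacing, image.origin)
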