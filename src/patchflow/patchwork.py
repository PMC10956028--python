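"""Tissue masking and pseudo-grid patch mining.

Large images (slides especially) are processed in fixed-size patches laid
out on a *pseudo-grid*: start coordinates at a fixed stride derived from
the patch size and the requested overlap, with the final window on each
axis clamped so it ends exactly at the image boundary — every pixel is
covered by at least one window, and no padding is ever needed.

For histology-style RGB images, a binary *tissue mask* computed at a
coarse downsample level filters the grid down to foreground coordinates:
a pixel counts as background when it is near-white on all three channels
or brighter than the Otsu threshold of the grayscale histogram; tissue is
the complement.  Patch windows whose tissue fraction falls below a
minimum are discarded before any model sees them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import DegenerateInputError
from .imagecore import GridImage, LabelMap, downsample

__all__ = [
    "PatchSpec",
    "PatchCoord",
    "TissueMask",
    "otsu_threshold",
    "tissue_mask",
    "pseudo_grid",
    "filter_by_tissue",
    "extract_patch",
    "sample_per_class",
]


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry: per-axis size plus an overlap fraction in [0, 1)."""

    patch_size: tuple
    overlap_fraction: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "patch_size", tuple(int(s) for s in self.patch_size))
        if any(s < 1 for s in self.patch_size):
            raise ValueError(f"patch_size entries must be >= 1, got {self.patch_size}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError(f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}")

    @property
    def stride(self) -> tuple:
        """Per-axis stride; floored at 1 so the grid is always finite."""
        return tuple(
            max(1, int(np.floor(s * (1.0 - self.overlap_fraction)))) for s in self.patch_size
        )


@dataclass(frozen=True)
class PatchCoord:
    """0-based window start, tagged with the downsample level it refers to."""

    start: tuple
    level_factor: int = 1

    def __post_init__(self):
        object.__setattr__(self, "start", tuple(int(s) for s in self.start))
        if self.level_factor < 1:
            raise ValueError("level_factor must be >= 1")


@dataclass
class TissueMask:
    """Binary foreground grid at a stated downsample level."""

    data: np.ndarray
    level_factor: int = 1

    def __post_init__(self):
        arr = np.asarray(self.data)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("tissue mask values must be 0/1")
        self.data = arr.astype(np.uint8)

    @property
    def tissue_fraction(self) -> float:
        return float(self.data.mean())


def otsu_threshold(values: Sequence[float], n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Builds an ``n_bins`` histogram over the value range and returns the
    interior bin edge that best separates the two classes — the classic
    foreground/background split for slide backgrounds.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if vals.size < 2 or vals.min() == vals.max():
        raise DegenerateInputError("otsu_threshold needs >= 2 distinct values")
    hist, edges = np.histogram(vals, bins=n_bins)
    p = hist.astype(np.float64) / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    omega = np.cumsum(p)  # P(class 0) when split after bin t
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0, posinf=-1.0)
    best = int(np.argmax(sigma_b))
    return float(edges[best + 1])


def tissue_mask(
    rgb: GridImage, level_factor: int = 1, white_cutoff: float = 0.9
) -> TissueMask:
    """Foreground mask of a histology-style RGB image at a coarse level.

    The image is block-mean downsampled by ``level_factor`` and rescaled
    to [0, 1] (dividing by 255 when values exceed 1).  A pixel is
    background when all three channels exceed ``white_cutoff`` or when its
    grayscale value (mean of R, G, B) exceeds the Otsu threshold of the
    grayscale histogram; tissue is the complement.
    """
    if rgb.ndim_spatial != 2 or rgb.n_channels != 3:
        raise ValueError(
            f"tissue_mask needs a 2D 3-channel image, got {rgb.n_channels} channels, "
            f"{rgb.ndim_spatial} spatial axes"
        )
    coarse = downsample(rgb, level_factor).data
    if coarse.max() > 1.0:
        coarse = coarse / 255.0
    white = np.all(coarse > white_cutoff, axis=0)
    gray = coarse.mean(axis=0)
    try:
        thr = otsu_threshold(gray.ravel())
        background = white | (gray > thr)
    except DegenerateInputError:
        # constant image: white-cutoff rule alone decides
        background = white
    return TissueMask((~background).astype(np.uint8), level_factor=level_factor)


def _axis_starts(length: int, size: int, stride: int) -> List[int]:
    starts = list(range(0, length - size + 1, stride))
    if starts[-1] + size < length:
        starts.append(length - size)  # clamp the final window to the boundary
    return starts


def pseudo_grid(shape: Sequence[int], spec: PatchSpec) -> List[PatchCoord]:
    """Row-major grid of patch start coordinates covering every pixel."""
    shape = tuple(int(n) for n in shape)
    if len(shape) != len(spec.patch_size):
        raise ValueError("shape and patch_size dimensionality differ")
    for ax, (n, s) in enumerate(zip(shape, spec.patch_size)):
        if n < s:
            raise ValueError(f"axis {ax}: image extent {n} smaller than patch size {s}")
    per_axis = [
        _axis_starts(n, s, st) for n, s, st in zip(shape, spec.patch_size, spec.stride)
    ]
    return [PatchCoord(start) for start in itertools.product(*per_axis)]


def filter_by_tissue(
    coords: Sequence[PatchCoord],
    mask: TissueMask,
    spec: PatchSpec,
    min_fraction: float,
) -> List[PatchCoord]:
    """Keep coordinates whose window tissue fraction is >= ``min_fraction``.

    Full-resolution coordinates are mapped onto the coarse mask by integer
    division; partially covered mask pixels at window edges are treated
    conservatively (excluded, i.e. counted as background).
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    if min_fraction == 0.0:
        return list(coords)
    lf = mask.level_factor
    kept = []
    for coord in coords:
        sl = []
        for ax, s0 in enumerate(coord.start):
            a0 = s0 // lf
            a1 = (s0 + spec.patch_size[ax]) // lf
            a1 = max(a1, a0 + 1)
            sl.append(slice(a0, a1))
        window = mask.data[tuple(sl)]
        frac = window.mean() if window.size else 0.0
        if frac >= min_fraction:
            kept.append(coord)
    return kept


def extract_patch(image: GridImage, coord: PatchCoord, spec: PatchSpec) -> GridImage:
    """Exact sub-grid at a coordinate; channel count is preserved."""
    sl = [slice(None)]
    for ax, s0 in enumerate(coord.start):
        s1 = s0 + spec.patch_size[ax]
        if s0 < 0 or s1 > image.spatial_shape[ax]:
            raise IndexError(
                f"patch [{s0}, {s1}) out of bounds on axis {ax} "
                f"of image shape {image.spatial_shape}"
            )
        sl.append(slice(s0, s1))
    return GridImage(image.data[tuple(sl)].copy(), image.spacing, image.origin)


def sample_per_class(
    coords: Sequence[PatchCoord],
    label: LabelMap,
    spec: PatchSpec,
    quota: dict,
    seed: int = 0,
) -> List[PatchCoord]:
    """Class-proportional patch sampling for classification mining.

    Each coordinate is assigned the majority label of its window; up to
    ``quota[class]`` coordinates per class are then drawn with a seeded
    generator (all of them when fewer are available).
    """
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for coord in coords:
        sl = tuple(
            slice(s0, s0 + sz) for s0, sz in zip(coord.start, spec.patch_size)
        )
        window = label.data[sl]
        vals, counts = np.unique(window, return_counts=True)
        by_class.setdefault(int(vals[np.argmax(counts)]), []).append(coord)
    out: List[PatchCoord] = []
    for cls in sorted(by_class):
        want = int(quota.get(cls, 0))
        pool = by_class[cls]
        if want >= len(pool):
            out.extend(pool)
        elif want > 0:
            idx = rng.choice(len(pool), size=want, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    return out
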