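"""Intensity and spatial harmonization, plus simple training augmentations.

Every intensity step operates channel-by-channel: channels are distinct
modalities (e.g. MRI sequences) whose scales are not comparable, so
statistics are never pooled across them.

Steps mirror the usual medical-imaging preprocessing vocabulary:

``threshold``
    Zero out values outside an intensity band (band-pass to zero).
``clip``
    Clamp values to the band's limits (e.g. CT windowing in Hounsfield
    units, such as clipping lung CT to [-900, -300] HU).
``rescale``
    Affine map of each channel onto a common output range such as [0, 1].
``zscore``
    Subtract the mean and divide by the (population) standard deviation,
    optionally computed over — and applied to — nonzero voxels only, which
    keeps a zero background at exactly zero.
``resample``
    Spatial resampling to a target voxel spacing or a target grid shape,
    with linear interpolation for intensities and nearest-neighbour for
    label maps.
``equalize``
    Global histogram equalization onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConfigError, NormalizationError
from .imagecore import GridImage, LabelMap

__all__ = [
    "IntensityBand",
    "PreprocSpec",
    "threshold_band",
    "clip_band",
    "rescale_range",
    "zscore_normalize",
    "resample",
    "equalize_global",
    "augment",
    "apply_preprocessing",
]


@dataclass(frozen=True)
class IntensityBand:
    """A closed intensity range [threshold_min, threshold_max]."""

    threshold_min: float
    threshold_max: float

    def __post_init__(self):
        if self.threshold_min > self.threshold_max:
            raise ValueError(
                f"threshold_min ({self.threshold_min}) exceeds "
                f"threshold_max ({self.threshold_max})"
            )


def threshold_band(image: GridImage, band: IntensityBand) -> GridImage:
    """Zero out intensities that fall outside the band."""
    data = image.data.copy()
    data[(data < band.threshold_min) | (data > band.threshold_max)] = 0.0
    return image.with_data(data)


def clip_band(image: GridImage, band: IntensityBand) -> GridImage:
    """Clamp intensities to the band's limits."""
    return image.with_data(np.clip(image.data, band.threshold_min, band.threshold_max))


def rescale_range(image: GridImage, out_min: float = 0.0, out_max: float = 1.0) -> GridImage:
    """Affinely map each channel onto [out_min, out_max].

    A constant channel maps to ``out_min`` everywhere (documented
    convention rather than an error).
    """
    if not out_min < out_max:
        raise ValueError(f"need out_min < out_max, got [{out_min}, {out_max}]")
    out = np.empty_like(image.data)
    for c in range(image.n_channels):
        ch = image.data[c]
        lo, hi = ch.min(), ch.max()
        if hi == lo:
            out[c] = out_min
        else:
            out[c] = (ch - lo) * ((out_max - out_min) / (hi - lo)) + out_min
    return image.with_data(out)


def zscore_normalize(image: GridImage, nonzero_only: bool = False) -> GridImage:
    """Standardize each channel to zero mean and unit (population) std.

    With ``nonzero_only``, statistics are computed over voxels with
    ``|x| > 0`` only and originally-zero voxels remain exactly 0 — the
    standard trick for skull-stripped MRI where the background is a large
    zero mass that would otherwise dominate the statistics.
    """
    out = np.empty_like(image.data)
    for c in range(image.n_channels):
        ch = image.data[c]
        sel = np.abs(ch) > 0 if nonzero_only else np.ones(ch.shape, dtype=bool)
        vals = ch[sel]
        if vals.size < 2:
            raise NormalizationError(
                f"channel {c}: need >= 2 selected voxels for z-score, got {vals.size}"
            )
        mu = vals.mean()
        sd = vals.std()  # population (divide-by-n) convention
        if sd == 0:
            raise NormalizationError(f"channel {c}: zero standard deviation")
        res = np.zeros_like(ch)
        res[sel] = (ch[sel] - mu) / sd
        out[c] = res
    return image.with_data(out)


def _resample_array(arr, zoom_factors, order):
    return ndimage.zoom(
        arr, zoom_factors, order=order, mode="nearest", grid_mode=True, prefilter=False
    )


def resample(
    image,
    target_spacing: Optional[Tuple[float, ...]] = None,
    target_shape: Optional[Tuple[int, ...]] = None,
    interpolation: str = "linear",
):
    """Resample to a target voxel spacing or grid shape.

    Exactly one of ``target_spacing`` / ``target_shape`` must be given.
    Intensities use linear (order-1) interpolation — monotone, so no
    overshoot near label edges; label maps always use nearest-neighbour
    and can contain no label absent from the input.  Physical extent
    (shape x spacing) is preserved within one voxel per axis.
    """
    if (target_spacing is None) == (target_shape is None):
        raise ValueError("give exactly one of target_spacing / target_shape")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be linear|nearest, got {interpolation!r}")

    is_label = isinstance(image, LabelMap)
    spacing = image.spacing
    shape = image.spatial_shape
    if target_spacing is not None:
        target_spacing = tuple(float(s) for s in target_spacing)
        if any(s <= 0 for s in target_spacing):
            raise ValueError(f"target spacing must be positive, got {target_spacing}")
        new_shape = tuple(
            max(1, int(round(n * sp / tsp)))
            for n, sp, tsp in zip(shape, spacing, target_spacing)
        )
        new_spacing = target_spacing
    else:
        new_shape = tuple(int(n) for n in target_shape)
        if any(n < 1 for n in new_shape):
            raise ValueError(f"target shape must be positive, got {target_shape}")
        new_spacing = tuple(n * sp / m for n, sp, m in zip(shape, spacing, new_shape))

    if new_shape == tuple(shape):
        if is_label:
            return LabelMap(image.data.copy(), spacing=new_spacing)
        return GridImage(image.data.copy(), new_spacing, image.origin)

    zoom = [m / n for m, n in zip(new_shape, shape)]
    if is_label:
        out = _resample_array(image.data.astype(np.float64), zoom, order=0)
        return LabelMap(np.round(out).astype(np.int64), spacing=new_spacing)
    order = 1 if interpolation == "linear" else 0
    out = np.stack([_resample_array(image.data[c], zoom, order) for c in range(image.n_channels)])
    return GridImage(out, new_spacing, image.origin)


def equalize_global(image: GridImage, n_bins: int = 256) -> GridImage:
    """Global histogram equalization of each channel onto [0, 1].

    Each value maps to the empirical CDF of its histogram bin, so the
    output is a monotone non-decreasing function of the input.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    out = np.empty_like(image.data)
    for c in range(image.n_channels):
        ch = image.data[c]
        lo, hi = ch.min(), ch.max()
        if hi == lo:
            out[c] = 1.0  # single bin: CDF is 1 everywhere
            continue
        hist, edges = np.histogram(ch, bins=n_bins, range=(lo, hi))
        cdf = np.cumsum(hist) / ch.size
        idx = np.minimum(((ch - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1)
        out[c] = cdf[idx]
    return image.with_data(out)


_AUGMENT_KINDS = ("flip", "rotate90", "noise", "blur")


def augment(
    image: GridImage,
    label: Optional[LabelMap],
    kind: str,
    params: Optional[dict] = None,
    rng_seed: int = 0,
):
    """Apply one training augmentation; deterministic given ``rng_seed``.

    Geometric kinds (flip, rotate90) transform image and label
    identically; intensity kinds (noise, blur) touch the image only.
    """
    params = dict(params or {})
    if kind not in _AUGMENT_KINDS:
        raise ValueError(f"unsupported augmentation {kind!r}; supported: {_AUGMENT_KINDS}")
    lab = label
    if kind == "flip":
        axis = int(params.get("axis", 0))
        data = np.flip(image.data, axis=axis + 1).copy()
        if lab is not None:
            lab = LabelMap(np.flip(lab.data, axis=axis).copy(), spacing=lab.spacing)
    elif kind == "rotate90":
        plane = tuple(int(a) for a in params.get("plane", (0, 1)))
        k = int(params.get("k", 1))
        data = np.rot90(image.data, k=k, axes=(plane[0] + 1, plane[1] + 1)).copy()
        if lab is not None:
            lab = LabelMap(np.rot90(lab.data, k=k, axes=plane).copy(), spacing=lab.spacing)
    elif kind == "noise":
        std = float(params.get("std", 0.0))
        rng = np.random.default_rng(rng_seed)
        data = image.data + (rng.normal(0.0, std, size=image.data.shape) if std > 0 else 0.0)
    else:  # blur
        sigma = float(params.get("sigma", 0.0))
        if sigma > 0:
            data = np.stack(
                [ndimage.gaussian_filter(image.data[c], sigma) for c in range(image.n_channels)]
            )
        else:
            data = image.data.copy()
    return GridImage(np.asarray(data, dtype=np.float64), image.spacing, image.origin), lab


@dataclass
class PreprocSpec:
    """An ordered list of preprocessing steps, each ``(name, params)``.

    Populated from the YAML config key ``preprocessing``; step names are
    the operations of this module.
    """

    steps: List[Tuple[str, dict]] = field(default_factory=list)

    _KNOWN = ("threshold", "clip", "rescale", "zscore", "resample", "equalize")

    def __post_init__(self):
        for name, _ in self.steps:
            if name not in self._KNOWN:
                raise ConfigError(f"unknown preprocessing step {name!r}; known: {self._KNOWN}")

    @classmethod
    def from_config(cls, entries) -> "PreprocSpec":
        """Parse the YAML ``preprocessing`` list (strings or one-key maps)."""
        steps = []
        for entry in entries or []:
            if isinstance(entry, str):
                steps.append((entry, {}))
            elif isinstance(entry, dict) and len(entry) == 1:
                ((name, params),) = entry.items()
                steps.append((name, dict(params or {})))
            else:
                raise ConfigError(f"bad preprocessing entry: {entry!r}")
        return cls(steps)


def apply_preprocessing(image: GridImage, spec: PreprocSpec) -> GridImage:
    """Run the steps of a :class:`PreprocSpec` in order."""
    for name, params in spec.steps:
        if name == "threshold":
            image = threshold_band(image, IntensityBand(params["min"], params["max"]))
        elif name == "clip":
            image = clip_band(image, IntensityBand(params["min"], params["max"]))
        elif name == "rescale":
            image = rescale_range(image, params.get("min", 0.0), params.get("max", 1.0))
        elif name == "zscore":
            image = zscore_normalize(image, nonzero_only=bool(params.get("nonzero_only", False)))
        elif name == "resample":
            image = resample(
                image,
                target_spacing=params.get("spacing"),
                target_shape=params.get("shape"),
            )
        elif name == "equalize":
            image = equalize_global(image, int(params.get("n_bins", 256)))
    return image
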