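"""Sliding-window inference, count-map stitching, fusion, post-processing.

Patch predictions are recombined with a *count map*: a running per-pixel
sum of predictions plus a tally of how many patches contributed to each
pixel.  Dividing the sum by the count once at the end (equivalently,
multiplying by the reciprocal count map) keeps every stitched probability
in [0, 1] no matter how the windows overlap.  Integer counts and a single
final division keep the arithmetic exact up to one rounding site.

Two stitching modes are supported for overlapping windows: ``average``
(the count-map normalization above) and ``crop`` (each patch claims only
its central region, with half the overlap margin trimmed per side; claims
never overwrite each other, and windows at the image border keep their
full extent so edges stay covered).

Fold-ensemble fusion combines the per-fold model outputs: per-pixel
majority vote for segmentation label maps, majority vote over predicted
classes for classification, and the arithmetic mean for regression —
ties always break toward the smallest class id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .imagecore import GridImage, LabelMap, ProbabilityMap
from .patchwork import (
    PatchCoord,
    PatchSpec,
    extract_patch,
    filter_by_tissue,
    pseudo_grid,
    tissue_mask,
)

__all__ = [
    "StitchAccumulator",
    "ModelContract",
    "stitch",
    "sliding_window_infer",
    "wsi_infer",
    "ensemble_fuse",
    "morphology",
    "map_labels",
]


class ModelContract:
    """Minimal fit/predict contract any pluggable model must satisfy.

    ``fit(train, validation, config)`` receives lists of
    ``(subject_id, GridImage, target)`` tuples and returns ``self``;
    ``predict_patch(patch)`` returns per-class per-pixel probabilities of
    shape ``(n_classes, *patch_spatial)`` for segmentation, a per-class
    probability vector for classification, or a scalar for regression.
    Implementations must be deterministic given their seed.  ``to_state``
    / ``from_state`` round-trip the fitted state through a plain dict for
    per-fold artifact storage.
    """

    task: str = "segmentation"

    def fit(self, train, validation, config):  # pragma: no cover - interface
        raise NotImplementedError

    def predict_patch(self, patch: GridImage):  # pragma: no cover - interface
        raise NotImplementedError

    def to_state(self) -> dict:  # pragma: no cover - interface
        raise NotImplementedError

    @classmethod
    def from_state(cls, state: dict) -> "ModelContract":  # pragma: no cover
        raise NotImplementedError


@dataclass
class StitchAccumulator:
    """Running per-pixel prediction sum and contribution count."""

    n_classes: int
    out_shape: tuple

    def __post_init__(self):
        self.out_shape = tuple(int(n) for n in self.out_shape)
        self.sum_map = np.zeros((self.n_classes,) + self.out_shape, dtype=np.float64)
        self.count_map = np.zeros(self.out_shape, dtype=np.int64)

    def add(self, coord: PatchCoord, pred: np.ndarray) -> None:
        """Accumulate one patch prediction of shape (n_classes, *patch)."""
        sl = tuple(
            slice(s0, s0 + n) for s0, n in zip(coord.start, pred.shape[1:])
        )
        self.sum_map[(slice(None),) + sl] += pred
        self.count_map[sl] += 1

    def normalize(self, classes: Sequence[int], background_index: int = 0) -> ProbabilityMap:
        """sum / count on covered pixels; background prob 1 elsewhere."""
        covered = self.count_map > 0
        prob = np.zeros_like(self.sum_map)
        np.divide(self.sum_map, self.count_map, out=prob, where=covered)
        prob[background_index, ~covered] = 1.0
        return ProbabilityMap(np.clip(prob, 0.0, 1.0), tuple(classes))


def stitch(
    patches: Sequence[Tuple[PatchCoord, np.ndarray]],
    out_shape: Sequence[int],
    mode: str = "average",
    spec: Optional[PatchSpec] = None,
    classes: Optional[Sequence[int]] = None,
) -> ProbabilityMap:
    """Recombine per-patch class predictions into one probability map.

    ``average`` divides the accumulated sum by the per-pixel contribution
    count.  ``crop`` trims ``floor(overlap * size / 2)`` per interior side
    of each patch (requires ``spec``) and lets the first patch claiming a
    pixel keep it.  Uncovered pixels carry probability 1 for background.
    """
    if mode not in ("average", "crop"):
        raise ValueError(f"mode must be average|crop, got {mode!r}")
    patches = list(patches)
    if not patches:
        raise ValueError("stitch needs at least one patch")
    n_classes = patches[0][1].shape[0]
    for _, pred in patches:
        if pred.shape[0] != n_classes:
            raise ValueError(
                f"inconsistent class counts across patches: {pred.shape[0]} vs {n_classes}"
            )
    out_shape = tuple(int(n) for n in out_shape)
    if classes is None:
        classes = tuple(range(n_classes))
    acc = StitchAccumulator(n_classes, out_shape)
    if mode == "average":
        for coord, pred in patches:
            acc.add(coord, np.asarray(pred, dtype=np.float64))
        return acc.normalize(classes)
    # crop mode
    if spec is None:
        raise ValueError("crop mode requires the PatchSpec to derive margins")
    claimed = np.zeros(out_shape, dtype=bool)
    for coord, pred in patches:
        pred = np.asarray(pred, dtype=np.float64)
        size = pred.shape[1:]
        inner = [slice(None)]
        outer = []
        for ax, (s0, n) in enumerate(zip(coord.start, size)):
            margin = int(np.floor(spec.overlap_fraction * spec.patch_size[ax] / 2))
            lo = margin if s0 > 0 else 0  # keep full patches at image borders
            hi = margin if s0 + n < out_shape[ax] else 0
            inner.append(slice(lo, n - hi))
            outer.append(slice(s0 + lo, s0 + n - hi))
        region = tuple(outer)
        free = ~claimed[region]
        acc.sum_map[(slice(None),) + region][:, free] = pred[tuple(inner)][:, free]
        acc.count_map[region][free] = 1
        claimed[region] |= True
    return acc.normalize(classes)


def sliding_window_infer(
    image: GridImage,
    model: ModelContract,
    spec: PatchSpec,
    mode: str = "average",
    classes: Optional[Sequence[int]] = None,
) -> ProbabilityMap:
    """Patch-based inference over the pseudo-grid of an image.

    Equivalent to extracting every grid patch, running the model's
    forward pass on each, and stitching the per-patch predictions; the
    process repeats until the complete image has been processed.
    """
    coords = pseudo_grid(image.spatial_shape, spec)
    patches = [
        (coord, np.asarray(model.predict_patch(extract_patch(image, coord, spec))))
        for coord in coords
    ]
    return stitch(patches, image.spatial_shape, mode=mode, spec=spec, classes=classes)


def wsi_infer(
    rgb: GridImage,
    model: ModelContract,
    spec: PatchSpec,
    mask_level: int = 4,
    min_fraction: float = 0.5,
    white_cutoff: float = 0.9,
    classes: Optional[Sequence[int]] = None,
) -> Tuple[ProbabilityMap, LabelMap]:
    """Histology-slide inference: mask, mine, predict, stitch, argmax.

    Pipeline: tissue mask at a coarse level -> pseudo-grid ->
    tissue-fraction filtering -> per-patch prediction -> average-mode
    stitch -> per-pixel argmax over classes on tissue pixels, background
    elsewhere.  An empty tissue mask produces a warning and an
    all-background output rather than an exception.
    """
    if rgb.ndim_spatial != 2 or rgb.n_channels != 3:
        raise ValueError("wsi_infer needs a 2D 3-channel image")
    mask = tissue_mask(rgb, level_factor=mask_level, white_cutoff=white_cutoff)
    n_classes = len(classes) if classes is not None else None
    coords = pseudo_grid(rgb.spatial_shape, spec)
    kept = filter_by_tissue(coords, mask, spec, min_fraction)
    if not kept:
        warnings.warn("empty tissue mask: emitting all-background output")
        if n_classes is None:
            n_classes = 2
            classes = (0, 1)
        prob = np.zeros((n_classes,) + rgb.spatial_shape)
        prob[0] = 1.0
        pm = ProbabilityMap(prob, tuple(classes))
        return pm, LabelMap(np.zeros(rgb.spatial_shape, dtype=np.int64))
    patches = [
        (coord, np.asarray(model.predict_patch(extract_patch(rgb, coord, spec))))
        for coord in kept
    ]
    if classes is None:
        classes = tuple(range(patches[0][1].shape[0]))
    prob_map = stitch(patches, rgb.spatial_shape, mode="average", classes=classes)
    # tissue mask upsampled back to full resolution to gate the argmax
    tissue_full = np.kron(mask.data, np.ones((mask_level, mask_level), dtype=np.uint8))
    tissue_full = tissue_full[: rgb.spatial_shape[0], : rgb.spatial_shape[1]]
    covered = tissue_full.astype(bool)
    labels = prob_map.argmax_labels().data
    labels[~covered] = 0
    return prob_map, LabelMap(labels)


def ensemble_fuse(per_fold_outputs: Sequence, task: str):
    """Fuse per-fold model outputs into a final prediction.

    Segmentation: per-pixel majority vote over fold LabelMaps.
    Classification: majority vote over predicted classes.  Regression:
    arithmetic mean of scalars.  Ties break toward the smallest class id.
    """
    outputs = list(per_fold_outputs)
    if not outputs:
        raise ValueError("ensemble_fuse needs at least one fold output")
    if task == "regression":
        return float(np.mean([float(v) for v in outputs]))
    if task == "classification":
        votes = np.bincount(np.asarray([int(v) for v in outputs]))
        return int(np.argmax(votes))  # argmax takes the smallest id on ties
    if task == "segmentation":
        stack = np.stack([lm.data for lm in outputs])
        n_labels = int(stack.max()) + 1
        counts = np.zeros((n_labels,) + stack.shape[1:], dtype=np.int32)
        for lab in range(n_labels):
            counts[lab] = (stack == lab).sum(axis=0)
        fused = np.argmax(counts, axis=0)
        return LabelMap(fused, spacing=outputs[0].spacing)
    raise ValueError(f"unknown task {task!r}")


_MORPH_OPS = ("dilate", "erode", "open", "close")


def morphology(mask: LabelMap, op: str, radius: int = 1) -> LabelMap:
    """Binary morphology with a box structuring element.

    ``open`` is erosion then dilation; ``close`` is dilation then erosion
    (useful for filling small holes in segmentation predictions).
    """
    if op not in _MORPH_OPS:
        raise ValueError(f"op must be one of {_MORPH_OPS}, got {op!r}")
    if not mask.labels <= {0, 1}:
        raise ValueError(f"morphology needs a binary 0/1 mask, got labels {mask.labels}")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    structure = np.ones((2 * radius + 1,) * mask.data.ndim, dtype=bool)
    binary = mask.data.astype(bool)
    if op == "dilate":
        out = ndimage.binary_dilation(binary, structure)
    elif op == "erode":
        out = ndimage.binary_erosion(binary, structure)
    elif op == "open":
        out = ndimage.binary_opening(binary, structure)
    else:
        out = ndimage.binary_closing(binary, structure)
    return LabelMap(out.astype(np.int64), spacing=mask.spacing)


def map_labels(mask: LabelMap, mapping: Dict[int, int]) -> LabelMap:
    """Substitute label values pointwise; unmapped labels pass through."""
    data = mask.data.copy()
    out = data.copy()
    for old, new in mapping.items():
        out[data == int(old)] = int(new)
    return LabelMap(out, spacing=mask.spacing)
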