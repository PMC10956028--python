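"""Synthetic cohorts and deterministic reference models.

The generators emulate the two image families the pipeline targets at
desk scale: (a) 3D multi-channel volumes containing ellipsoidal
foreground blobs whose classes carry distinct intensity signatures over
a zero background plus Gaussian noise, and (b) large 2D RGB pseudo-slides
with a near-white background, pink "tissue" regions and purple "lesion"
disks embedded in the tissue.

Class intensity means are separated by ten noise standard deviations, so
the classes are essentially perfectly separable: any end-to-end failure
on these cohorts points at pipeline plumbing, not at modeling capacity.
Every generator is a pure function of (spec, seed, subject_index); each
subject gets an independent random stream derived from the pair
``(seed, subject_index)`` so cohorts carry no cross-subject correlation.

The reference models are deterministic single-shot stand-ins satisfying
the fit/predict model contract:

* ``ThresholdSegmenter`` — learns per-class mean channel intensities
  from the training labels and predicts the nearest class mean per pixel;
* ``MeanRegressor`` — predicts the training-target mean;
* ``MajorityClassifier`` — predicts the training-majority class;
* ``OracleSegmenter`` — test-only model with *known* class signatures
  that emits ground-truth one-hot output on separable data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .imagecore import GridImage, LabelMap, write_image
from .stitcher import ModelContract

__all__ = [
    "SyntheticCohortSpec",
    "make_volume",
    "make_pseudo_wsi",
    "make_manifest",
    "reference_models",
    "ThresholdSegmenter",
    "MeanRegressor",
    "MajorityClassifier",
    "OracleSegmenter",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort."""

    n_subjects: int = 10
    task: str = "segmentation"
    ndim: int = 3
    shape: tuple = (32, 32, 32)
    n_channels: int = 1
    n_classes: int = 2
    noise_std: float = 0.05
    seed: int = 42

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(s < 8 for s in self.shape):
            raise ValueError("every shape entry must be >= 8")
        if self.task not in ("segmentation", "classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if len(self.shape) != self.ndim:
            raise ValueError("shape length must equal ndim")

    @property
    def delta(self) -> float:
        """Class-mean separation: 10 noise standard deviations (1.0 when
        noiseless so classes remain distinguishable)."""
        return 10.0 * self.noise_std if self.noise_std > 0 else 1.0


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def make_volume(spec: SyntheticCohortSpec, subject_index: int) -> Tuple[GridImage, LabelMap]:
    """One segmentation subject: blobs of class c at mean intensity c·Δ.

    Each foreground class 1..n_classes-1 contributes one ellipsoidal blob
    over a zero background; Gaussian noise of ``spec.noise_std`` is added
    to every channel.  Blob placement retries with shifted centers until
    blobs do not collide.  Deterministic per (seed, subject_index).
    """
    rng = _subject_rng(spec.seed, subject_index)
    shape = spec.shape
    label = np.zeros(shape, dtype=np.int64)
    for cls in range(1, spec.n_classes):
        placed = False
        for _attempt in range(64):
            radii = [rng.uniform(0.08, 0.16) * n for n in shape]
            center = [rng.uniform(r + 1, n - r - 1) for r, n in zip(radii, shape)]
            blob = _ellipsoid_mask(shape, center, radii)
            if not (blob & (label > 0)).any():
                label[blob] = cls
                placed = True
                break
        if not placed:  # fall back: shift deterministically toward a free corner
            blob = _ellipsoid_mask(
                shape,
                [n * (0.2 + 0.6 * cls / spec.n_classes) for n in shape],
                [0.05 * n for n in shape],
            )
            label[blob & (label == 0)] = cls
    clean = label.astype(np.float64) * spec.delta
    data = np.stack([clean] * spec.n_channels)
    if spec.noise_std > 0:
        data = data + rng.normal(0.0, spec.noise_std, size=data.shape)
    spacing = (1.0,) * spec.ndim
    return GridImage(data, spacing), LabelMap(label, spacing=spacing)


def _disk(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


# class palette of the pseudo-slide, channel-first RGB in [0, 1]
_WSI_COLORS = {
    0: (0.97, 0.97, 0.97),  # near-white slide background
    1: (0.90, 0.55, 0.70),  # pink tissue
    2: (0.50, 0.30, 0.60),  # purple lesion
}


def make_pseudo_wsi(
    size: Tuple[int, int], lesion_fraction: float = 0.1, seed: int = 0
) -> Tuple[GridImage, LabelMap]:
    """A flat pseudo-slide: white background, pink tissue, purple lesions.

    Tissue is a handful of large overlapping disks; lesion disks are
    placed inside tissue until they occupy about ``lesion_fraction`` of
    the tissue area.  Labels: 0 background, 1 tissue, 2 lesion.
    """
    H, W = int(size[0]), int(size[1])
    if H < 256 or W < 256:
        raise ValueError("pseudo-WSI must be at least 256x256")
    if not 0.0 < lesion_fraction < 1.0:
        raise ValueError(f"lesion_fraction must be in (0, 1), got {lesion_fraction}")
    rng = np.random.default_rng(seed)
    label = np.zeros((H, W), dtype=np.int64)
    for _ in range(4):
        r = rng.uniform(0.12, 0.2) * min(H, W)
        c = (rng.uniform(r, H - r), rng.uniform(r, W - r))
        label[_disk((H, W), c, r)] = 1
    tissue_area = int((label == 1).sum())
    target = lesion_fraction * tissue_area
    lesion_area = 0
    for _ in range(256):
        if lesion_area >= target:
            break
        r = rng.uniform(0.02, 0.05) * min(H, W)
        c = (rng.uniform(r, H - r), rng.uniform(r, W - r))
        d = _disk((H, W), c, r)
        if (label[d] == 1).all():  # lesions live strictly inside tissue
            label[d] = 2
            lesion_area = int((label == 2).sum())
    data = np.zeros((3, H, W), dtype=np.float64)
    for cls, color in _WSI_COLORS.items():
        sel = label == cls
        for ch in range(3):
            data[ch][sel] = color[ch]
    # slight deterministic texture so the background is "near-white", >= 0.95
    noise = rng.uniform(0.0, 0.02, size=(H, W))
    data[:, label == 0] += noise[label == 0]
    data = np.clip(data, 0.0, 1.0)
    return GridImage(data, (1.0, 1.0)), LabelMap(label, spacing=(1.0, 1.0))


def make_manifest(spec: SyntheticCohortSpec, out_dir) -> Path:
    """Write a full cohort to disk plus its manifest CSV.

    Images go to NIfTI (3D) or TIFF (2D); segmentation subjects get a
    Label column, regression subjects a ValueToPredict equal to the total
    blob volume scaled to [0, 1], classification subjects the dominant
    blob class.  Deterministic for a fixed spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if spec.ndim == 3 else ".tif"
    rows = []
    for idx in range(spec.n_subjects):
        image, label = make_volume(spec, idx)
        sid = f"sub-{idx:03d}"
        channel_paths = []
        for ch in range(spec.n_channels):
            p = out_dir / f"{sid}_ch{ch}{ext}"
            write_image(image.channel(ch), p)
            channel_paths.append(str(p))
        row = {"SubjectID": sid}
        for ch, p in enumerate(channel_paths):
            row[f"Channel_{ch}"] = p
        if spec.task == "segmentation":
            lp = out_dir / f"{sid}_label{ext}"
            write_image(label, lp)
            row["Label"] = str(lp)
        elif spec.task == "regression":
            row["ValueToPredict"] = (label.data > 0).sum() / label.data.size
        else:  # classification: dominant foreground blob class
            fg, counts = np.unique(label.data[label.data > 0], return_counts=True)
            row["ValueToPredict"] = int(fg[np.argmax(counts)]) if fg.size else 0
        rows.append(row)
    manifest_path = out_dir / "manifest.csv"
    fieldnames = list(rows[0].keys())
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path


def _nearest_class_probs(patch: GridImage, signatures: Dict[int, np.ndarray]) -> np.ndarray:
    """One-hot per-pixel probabilities of the nearest class signature."""
    classes = sorted(signatures)
    sig = np.stack([np.asarray(signatures[c], dtype=np.float64) for c in classes])
    # distances: (n_classes, *spatial)
    diffs = patch.data[None] - sig[(...,) + (None,) * patch.ndim_spatial]
    dist = np.sqrt((diffs**2).sum(axis=1))
    nearest = np.argmin(dist, axis=0)
    probs = np.zeros((len(classes),) + patch.spatial_shape, dtype=np.float64)
    for k in range(len(classes)):
        probs[k][nearest == k] = 1.0
    return probs


class ThresholdSegmenter(ModelContract):
    """Learns per-class mean channel intensities; predicts nearest mean."""

    task = "segmentation"
    name = "threshold_segmenter"

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self.signatures: Optional[Dict[int, np.ndarray]] = None

    def fit(self, train, validation, config=None):
        sums: Dict[int, np.ndarray] = {}
        counts: Dict[int, int] = {}
        for _sid, image, target in train:
            if not isinstance(target, LabelMap):
                raise TypeError("ThresholdSegmenter needs LabelMap targets")
            for cls in sorted(target.labels):
                sel = target.data == cls
                vec = image.data[:, sel].sum(axis=1)
                sums[cls] = sums.get(cls, 0) + vec
                counts[cls] = counts.get(cls, 0) + int(sel.sum())
        self.signatures = {c: sums[c] / counts[c] for c in sums if counts[c] > 0}
        return self

    def predict_patch(self, patch: GridImage) -> np.ndarray:
        if self.signatures is None:
            raise RuntimeError("model is not fitted")
        return _nearest_class_probs(patch, self.signatures)

    def to_state(self) -> dict:
        return {
            "model": self.name,
            "seed": self.seed,
            "signatures": {str(c): list(map(float, v)) for c, v in self.signatures.items()},
        }

    @classmethod
    def from_state(cls, state: dict) -> "ThresholdSegmenter":
        obj = cls(seed=state.get("seed", 0))
        obj.signatures = {int(c): np.asarray(v) for c, v in state["signatures"].items()}
        return obj


class OracleSegmenter(ModelContract):
    """Test-only segmenter with known class signatures (no fitting).

    On data whose classes carry exactly those signatures it emits the
    ground-truth one-hot map, making it an end-to-end plumbing oracle.
    """

    task = "segmentation"
    name = "oracle_segmenter"

    def __init__(self, signatures: Optional[Dict[int, np.ndarray]] = None, seed: int = 0):
        self.seed = int(seed)
        self.signatures = (
            {int(c): np.asarray(v, dtype=np.float64) for c, v in signatures.items()}
            if signatures
            else None
        )

    @classmethod
    def for_cohort(cls, spec: SyntheticCohortSpec) -> "OracleSegmenter":
        sig = {
            c: np.full(spec.n_channels, c * spec.delta) for c in range(spec.n_classes)
        }
        return cls(sig)

    @classmethod
    def for_pseudo_wsi(cls) -> "OracleSegmenter":
        return cls({c: np.asarray(v) for c, v in _WSI_COLORS.items()})

    def fit(self, train, validation, config=None):
        if self.signatures is None:
            # infer exact signatures from the (noiseless) training labels
            ThresholdSegmenter.fit(self, train, validation, config)
        return self

    predict_patch = ThresholdSegmenter.predict_patch
    to_state = ThresholdSegmenter.to_state

    @classmethod
    def from_state(cls, state: dict) -> "OracleSegmenter":
        return cls(
            {int(c): np.asarray(v) for c, v in state["signatures"].items()},
            seed=state.get("seed", 0),
        )


class MeanRegressor(ModelContract):
    """Predicts the mean of the training targets for every input."""

    task = "regression"
    name = "mean_regressor"

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self.mean_: Optional[float] = None

    def fit(self, train, validation, config=None):
        targets = [float(t) for _sid, _img, t in train]
        if not targets:
            raise ValueError("MeanRegressor needs at least one training target")
        self.mean_ = float(np.mean(targets))
        return self

    def predict_patch(self, patch: GridImage) -> float:
        if self.mean_ is None:
            raise RuntimeError("model is not fitted")
        return self.mean_

    def to_state(self) -> dict:
        return {"model": self.name, "seed": self.seed, "mean": self.mean_}

    @classmethod
    def from_state(cls, state: dict) -> "MeanRegressor":
        obj = cls(seed=state.get("seed", 0))
        obj.mean_ = state["mean"]
        return obj


class MajorityClassifier(ModelContract):
    """Predicts the training-majority class, ties toward the smallest id."""

    task = "classification"
    name = "majority_classifier"

    def __init__(self, seed: int = 0, n_classes: int = 2):
        self.seed = int(seed)
        self.n_classes = int(n_classes)
        self.majority_: Optional[int] = None

    def fit(self, train, validation, config=None):
        targets = np.asarray([int(t) for _sid, _img, t in train])
        if targets.size == 0:
            raise ValueError("MajorityClassifier needs training targets")
        self.n_classes = max(self.n_classes, int(targets.max()) + 1)
        self.majority_ = int(np.argmax(np.bincount(targets, minlength=self.n_classes)))
        return self

    def predict_patch(self, patch: GridImage) -> np.ndarray:
        if self.majority_ is None:
            raise RuntimeError("model is not fitted")
        probs = np.zeros(self.n_classes)
        probs[self.majority_] = 1.0
        return probs

    def to_state(self) -> dict:
        return {
            "model": self.name,
            "seed": self.seed,
            "majority": self.majority_,
            "n_classes": self.n_classes,
        }

    @classmethod
    def from_state(cls, state: dict) -> "MajorityClassifier":
        obj = cls(seed=state.get("seed", 0), n_classes=state.get("n_classes", 2))
        obj.majority_ = state["majority"]
        return obj


def reference_models() -> Dict[str, type]:
    """Registry of the deterministic reference model classes by name."""
    return {
        ThresholdSegmenter.name: ThresholdSegmenter,
        OracleSegmenter.name: OracleSegmenter,
        MeanRegressor.name: MeanRegressor,
        MajorityClassifier.name: MajorityClassifier,
    }
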