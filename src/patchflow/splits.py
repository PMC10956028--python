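"""Subject-level nested cross-validation and class-imbalance penalties.

Nested k-fold cross-validation partitions the cohort twice: an outer loop
holds out non-overlapping, equally-sized test subsets, and for each outer
fold an inner loop holds out validation subsets from the remaining
subjects.  With ``k_outer = k_inner = 5`` every (outer, inner) pair uses
20% of the cohort for testing, 16% for validation and 64% for training,
and the plan contains 25 pairs in total.

Splitting always operates on subject identifiers — never on patches or
slices — so no subject can leak between the partitions of a fold.

The class-imbalance penalty weights a loss inversely to class frequency:

    p_c = 1 - n_c / N

where ``n_c`` counts instances of class ``c`` among ``N`` samples (cases
for classification, voxels for segmentation).  For ``C`` classes the
weights always sum to ``C - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import CohortSizeError, ManifestError
from .imagecore import LabelMap

__all__ = [
    "SubjectRecord",
    "SplitPlan",
    "ClassCensus",
    "PenaltyWeights",
    "make_nested_splits",
    "class_penalties",
    "segmentation_census",
]


@dataclass
class SubjectRecord:
    """One manifest row: a subject id, its image channels, and a target.

    ``target`` is a label-mask path (segmentation), an integer class index
    (classification) or a real scalar (regression).
    """

    subject_id: str
    channel_paths: List[str]
    target: Union[str, int, float]

    def __post_init__(self):
        if not self.channel_paths:
            raise ManifestError(f"subject {self.subject_id!r} has no channel paths")


@dataclass
class SplitPlan:
    """Role assignment (train/validation/test) for every (outer, inner) pair."""

    k_outer: int
    k_inner: int
    seed: int
    assignment: Dict[Tuple[int, int], Dict[str, List[str]]]

    def pairs(self):
        """All (outer_fold, inner_fold) keys in deterministic order."""
        return sorted(self.assignment.keys())

    def roles(self, outer: int, inner: int) -> Dict[str, List[str]]:
        return self.assignment[(outer, inner)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit table: subject_id, outer_fold, inner_fold, role."""
        rows = []
        for (o, i), parts in sorted(self.assignment.items()):
            for role in ("train", "validation", "test"):
                for sid in parts[role]:
                    rows.append((sid, o, i, role))
        return pd.DataFrame(rows, columns=["subject_id", "outer_fold", "inner_fold", "role"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _chunks(ids: np.ndarray, k: int) -> List[np.ndarray]:
    # np.array_split gives sizes differing by <= 1, earlier chunks larger
    return np.array_split(ids, k)


def make_nested_splits(
    subject_ids: Sequence[str], k_outer: int, k_inner: int, seed: int
) -> SplitPlan:
    """Build a nested k-fold split plan over subject ids.

    Subject ids are shuffled once with a seeded generator and assigned to
    outer folds contiguously in shuffled order (sizes differ by at most
    one, earlier folds take the extra subject); inner folds partition each
    outer remainder the same way.  ``k_outer = 1`` means no held-out test
    set (single-fold training); ``k_inner = 1`` means no held-out
    validation set.
    """
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ManifestError("subject ids must be unique")
    if k_outer < 1 or k_inner < 1:
        raise ValueError("k_outer and k_inner must be >= 1")
    minimum = k_outer * k_inner
    if len(ids) < minimum:
        raise CohortSizeError(
            f"need at least k_outer * k_inner = {minimum} subjects "
            f"for ({k_outer}, {k_inner}) nesting, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = np.array(ids, dtype=object)
    rng.shuffle(shuffled)

    if k_outer == 1:
        outer_tests = [np.array([], dtype=object)]
    else:
        outer_tests = _chunks(shuffled, k_outer)

    assignment = {}
    for o, test_ids in enumerate(outer_tests):
        test_set = set(test_ids.tolist())
        remainder = np.array([s for s in shuffled if s not in test_set], dtype=object)
        if k_inner == 1:
            inner_vals = [np.array([], dtype=object)]
        else:
            inner_vals = _chunks(remainder, k_inner)
        for i, val_ids in enumerate(inner_vals):
            val_set = set(val_ids.tolist())
            train = [s for s in remainder if s not in val_set]
            assignment[(o, i)] = {
                "train": list(train),
                "validation": list(val_ids),
                "test": list(test_ids),
            }
    return SplitPlan(k_outer=k_outer, k_inner=k_inner, seed=seed, assignment=assignment)


@dataclass
class ClassCensus:
    """Per-class instance counts ``n_c`` and the total sample count ``N``."""

    counts: Dict[int, int]

    def __post_init__(self):
        self.counts = {int(c): int(n) for c, n in self.counts.items()}
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("class counts must be non-negative")
        if self.N <= 0:
            raise ValueError("census total N must be positive")

    @property
    def N(self) -> int:
        return sum(self.counts.values())


@dataclass
class PenaltyWeights:
    """Loss penalty per class; for C classes the weights sum to C - 1."""

    weights: Dict[int, float]

    def __getitem__(self, class_id: int) -> float:
        return self.weights[class_id]


def class_penalties(census: ClassCensus) -> PenaltyWeights:
    """Inverse-frequency penalty weights ``p_c = 1 - n_c / N``.

    Rarer classes get a larger penalty: a 100-case cohort with 10 cases of
    class 0 and 90 of class 1 yields weights 0.9 and 0.1.  A zero-count
    class gets exactly 1 (no re-normalization; an explicit penalty map in
    the experiment config overrides this when needed).
    """
    N = census.N
    return PenaltyWeights({c: 1.0 - n / N for c, n in census.counts.items()})


def segmentation_census(labels: Sequence[LabelMap], classes: Sequence[int]) -> ClassCensus:
    """Voxel-level class census over a set of label maps."""
    classes = [int(c) for c in classes]
    counts = {c: 0 for c in classes}
    known = set(classes)
    for lm in labels:
        vals, n = np.unique(lm.data, return_counts=True)
        for v, k in zip(vals.tolist(), n.tolist()):
            if v not in known:
                raise ValueError(f"label value {v} not in declared classes {sorted(known)}")
            counts[v] += int(k)
    return ClassCensus(counts)
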