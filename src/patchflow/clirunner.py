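"""Zero/low-code experiment runner and command-line interface.

An experiment is fully described by two files: a CSV *manifest* listing
subject ids, the full paths of each subject's image channels, and either
a label-mask path (segmentation) or a value to predict (classification /
regression); and a YAML *config* parameterizing the task, the model, the
preprocessing, the augmentations, the nested cross-validation layout and
the inference options.  ``run_experiment`` executes the full nested-CV
loop over any registered model satisfying the fit/predict contract and
writes per-fold statistics CSVs; ``run_inference`` applies saved fold
models and fuses their outputs into a final prediction.

All randomness (splits, augmentation draws, model seeds) flows from the
single config seed through named substreams, so repeated runs with the
same config, manifest, and seed are byte-identical.
"""

from __future__ import annotations

import difflib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ManifestError, PatchflowError
from .harmonize import PreprocSpec, apply_preprocessing, augment
from .imagecore import GridImage, LabelMap, read_image, read_label, write_image
from .metrics import (
    MetricReport,
    dice,
    hausdorff95,
    mse,
    multiclass_balanced_accuracy,
)
from .patchwork import PatchSpec, extract_patch, pseudo_grid
from .splits import (
    ClassCensus,
    SplitPlan,
    SubjectRecord,
    class_penalties,
    make_nested_splits,
    segmentation_census,
)
from .stitcher import ensemble_fuse, sliding_window_infer, wsi_infer
from .synthfix import SyntheticCohortSpec, make_manifest, reference_models

__all__ = [
    "ExperimentConfig",
    "FoldResult",
    "parse_manifest",
    "load_config",
    "run_experiment",
    "run_inference",
    "main",
]

_TASKS = ("segmentation", "classification", "regression")

_CONFIG_KEYS = (
    "task",
    "model_name",
    "patch_size",
    "overlap",
    "preprocessing",
    "augmentations",
    "nested_training",
    "penalty",
    "seed",
    "inference",
    "classes",
    "version",
)


@dataclass
class ExperimentConfig:
    """Validated, fully-defaulted experiment configuration."""

    task: str
    model_name: str
    patch_size: tuple
    overlap: float = 0.0
    preprocessing: PreprocSpec = field(default_factory=PreprocSpec)
    augmentations: List[dict] = field(default_factory=list)
    k_outer: int = 1
    k_inner: int = 1
    penalty: Union[str, Dict[int, float]] = "auto"
    seed: int = 42
    inference: Dict = field(default_factory=lambda: {"mode": "average"})
    classes: List[int] = field(default_factory=lambda: [0, 1])
    version: str = __version__

    def __post_init__(self):
        if self.task not in _TASKS:
            raise ConfigError(f"task must be one of {_TASKS}, got {self.task!r}")
        self.patch_size = tuple(int(s) for s in self.patch_size)
        if self.k_outer < 1 or self.k_inner < 1:
            raise ConfigError("nested_training values must be >= 1")
        for aug in self.augmentations:
            p = float(aug.get("probability", 1.0))
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"augmentation probability {p} outside [0, 1]")
        if not self.version:
            raise ConfigError("config version must be present")

    @property
    def patch_spec(self) -> PatchSpec:
        return PatchSpec(self.patch_size, self.overlap)


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config.

    Unknown keys are rejected with a closest-match suggestion; defaults
    are filled for everything except task, model_name, and patch_size.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a YAML mapping: {path}")
    for key in raw:
        if key not in _CONFIG_KEYS:
            hint = difflib.get_close_matches(key, _CONFIG_KEYS, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suffix}")
    if "task" not in raw:
        raise ConfigError("config is missing required key 'task'")
    for key in ("model_name", "patch_size"):
        if key not in raw:
            raise ConfigError(f"config is missing required key {key!r}")
    nested = raw.get("nested_training") or {}
    penalty = raw.get("penalty", "auto")
    if isinstance(penalty, dict):
        penalty = {int(c): float(v) for c, v in penalty.items()}
    return ExperimentConfig(
        task=raw["task"],
        model_name=str(raw["model_name"]),
        patch_size=raw["patch_size"],
        overlap=float(raw.get("overlap", 0.0)),
        preprocessing=PreprocSpec.from_config(raw.get("preprocessing")),
        augmentations=list(raw.get("augmentations") or []),
        k_outer=int(nested.get("testing", 1)),
        k_inner=int(nested.get("validation", 1)),
        penalty=penalty,
        seed=int(raw.get("seed", 42)),
        inference={"mode": "average", **(raw.get("inference") or {})},
        classes=[int(c) for c in raw.get("classes", [0, 1])],
        version=str(raw.get("version", __version__)),
    )


def parse_manifest(path, require_target: bool = True) -> List[SubjectRecord]:
    """Parse a subject manifest CSV into SubjectRecords.

    Recognized columns: ``SubjectID``; ``Channel_0..Channel_k`` (sorted
    by index, not file order); exactly one of ``Label`` (mask path) or
    ``ValueToPredict`` (number or class index).  Every referenced path is
    checked for existence.
    """
    frame = pd.read_csv(path, dtype={"SubjectID": str})
    if "SubjectID" not in frame.columns:
        raise ManifestError(f"manifest is missing required column 'SubjectID': {path}")
    channel_cols = sorted(
        (c for c in frame.columns if c.startswith("Channel_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    if not channel_cols:
        raise ManifestError(f"manifest has no Channel_<k> columns: {path}")
    has_label = "Label" in frame.columns
    has_value = "ValueToPredict" in frame.columns
    if has_label and has_value:
        raise ManifestError("manifest must have exactly one of Label / ValueToPredict")
    if require_target and not (has_label or has_value):
        raise ManifestError("manifest needs a Label or ValueToPredict column")
    if frame["SubjectID"].duplicated().any():
        dupes = frame.loc[frame["SubjectID"].duplicated(), "SubjectID"].tolist()
        raise ManifestError(f"duplicate subject ids: {dupes}")
    records = []
    for _, row in frame.iterrows():
        sid = row["SubjectID"]
        paths = []
        for col in channel_cols:
            p = str(row[col])
            if not Path(p).exists():
                raise ManifestError(f"subject {sid!r}, column {col}: missing file {p}")
            paths.append(p)
        if has_label:
            target = str(row["Label"])
            if not Path(target).exists():
                raise ManifestError(f"subject {sid!r}, column Label: missing file {target}")
        elif has_value:
            target = float(row["ValueToPredict"])
        else:
            target = None
        records.append(SubjectRecord(subject_id=sid, channel_paths=paths, target=target))
    return records


def _load_subject(
    record: SubjectRecord, config: ExperimentConfig
) -> Tuple[GridImage, Union[LabelMap, float, None]]:
    """Read a subject's channels into one multi-channel image, preprocess,
    and resolve the target."""
    channels = [read_image(p) for p in record.channel_paths]
    data = np.concatenate([c.data for c in channels], axis=0)
    image = GridImage(data, channels[0].spacing, channels[0].origin)
    image = apply_preprocessing(image, config.preprocessing)
    target = record.target
    if isinstance(target, str):
        target = read_label(target)
    elif target is not None and config.task == "classification":
        target = int(target)
    return image, target


def _augment_training_sample(image, label, config: ExperimentConfig, rng):
    """One seeded uniform draw per configured transform per sample."""
    for aug in config.augmentations:
        p = float(aug.get("probability", 1.0))
        if rng.uniform() < p:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            image, label = augment(
                image, label, aug["kind"], aug.get("params", {}), rng_seed=sub_seed
            )
    return image, label


def _fold_census(train_data, config: ExperimentConfig) -> Optional[ClassCensus]:
    if config.task == "segmentation":
        labels = [t for _sid, _img, t in train_data]
        return segmentation_census(labels, config.classes)
    if config.task == "classification":
        counts = {c: 0 for c in config.classes}
        for _sid, _img, t in train_data:
            counts[int(t)] = counts.get(int(t), 0) + 1
        return ClassCensus(counts)
    return None


def _classify_image(image, model, spec: PatchSpec) -> int:
    """Image-level class: argmax of the mean per-patch probability."""
    coords = pseudo_grid(image.spatial_shape, spec)
    probs = np.mean(
        [np.asarray(model.predict_patch(extract_patch(image, c, spec))) for c in coords],
        axis=0,
    )
    return int(np.argmax(probs))


def _regress_image(image, model, spec: PatchSpec) -> float:
    coords = pseudo_grid(image.spatial_shape, spec)
    return float(
        np.mean([float(model.predict_patch(extract_patch(image, c, spec))) for c in coords])
    )


def _segment_image(image, model, config: ExperimentConfig) -> LabelMap:
    use_wsi = config.inference.get(
        "histology", image.ndim_spatial == 2 and image.n_channels == 3
    )
    if use_wsi:
        _pm, pred = wsi_infer(
            image,
            model,
            config.patch_spec,
            mask_level=int(config.inference.get("mask_level", 4)),
            min_fraction=float(config.inference.get("min_tissue_fraction", 0.5)),
            classes=config.classes,
        )
        return pred
    pm = sliding_window_infer(
        image,
        model,
        config.patch_spec,
        mode=config.inference.get("mode", "average"),
        classes=config.classes,
    )
    return pm.argmax_labels(spacing=image.spacing)


@dataclass
class FoldResult:
    """Outcome of one (outer, inner) fold: predictions, metrics, artifact."""

    outer_fold: int
    inner_fold: int
    predictions: Dict[str, Dict[str, object]]  # phase -> subject -> prediction
    report: MetricReport
    model_path: Optional[Path] = None
    penalties: Optional[Dict[int, float]] = None


def _evaluate_phase(
    phase: str,
    subjects: List[str],
    data: Dict[str, tuple],
    model,
    config: ExperimentConfig,
    report: MetricReport,
    o: int,
    i: int,
) -> Dict[str, object]:
    preds: Dict[str, object] = {}
    if config.task == "segmentation":
        for sid in subjects:
            image, gt = data[sid]
            pred = _segment_image(image, model, config)
            preds[sid] = pred
            for cls in [c for c in config.classes if c != 0]:
                report.add(f"{phase}_dice", dice(gt, pred, cls), o, i, sid, cls)
    elif config.task == "classification":
        gts, outs = [], []
        for sid in subjects:
            image, gt = data[sid]
            pred = _classify_image(image, model, config.patch_spec)
            preds[sid] = pred
            gts.append(int(gt))
            outs.append(pred)
            report.add(f"{phase}_correct", float(pred == int(gt)), o, i, sid)
        if subjects:
            report.add(
                f"{phase}_balanced_accuracy",
                multiclass_balanced_accuracy(gts, outs),
                o,
                i,
            )
    else:  # regression
        gts, outs = [], []
        for sid in subjects:
            image, gt = data[sid]
            pred = _regress_image(image, model, config.patch_spec)
            preds[sid] = pred
            gts.append(float(gt))
            outs.append(pred)
            report.add(f"{phase}_squared_error", (pred - float(gt)) ** 2, o, i, sid)
        if subjects:
            report.add(f"{phase}_mse", mse(gts, outs), o, i)
    return preds


def _run_fold(
    o: int,
    i: int,
    roles: Dict[str, List[str]],
    data: Dict[str, tuple],
    config: ExperimentConfig,
    model_registry: Dict[str, type],
    out_dir: Path,
) -> FoldResult:
    train_ids, val_ids, test_ids = roles["train"], roles["validation"], roles["test"]
    # leakage guard: the held-out subjects must never enter training
    assert not (set(test_ids) & set(train_ids)), "test subjects leaked into training"
    assert not (set(test_ids) & set(val_ids)), "test subjects leaked into validation"
    assert not (set(val_ids) & set(train_ids)), "validation subjects leaked into training"

    fold_rng = np.random.default_rng(np.random.SeedSequence([config.seed, o, i]))
    train_data = []
    for sid in train_ids:
        image, target = data[sid]
        label = target if isinstance(target, LabelMap) else None
        image, label = _augment_training_sample(image, label, config, fold_rng)
        train_data.append((sid, image, label if label is not None else target))
    val_data = [(sid,) + data[sid] for sid in val_ids]

    census = _fold_census(train_data, config)
    if config.penalty == "auto":
        penalties = dict(class_penalties(census).weights) if census else None
    else:
        penalties = dict(config.penalty)

    model_seed = int(fold_rng.integers(0, 2**31 - 1))
    model_cls = model_registry[config.model_name]
    model = model_cls(seed=model_seed)
    model.fit(train_data, val_data, {"penalties": penalties, "classes": config.classes})

    report = MetricReport()
    predictions = {
        "validation": _evaluate_phase("validation", val_ids, data, model, config, report, o, i),
        "test": _evaluate_phase("test", test_ids, data, model, config, report, o, i),
    }

    fold_dir = out_dir / "models" / f"fold_{o}_{i}"
    fold_dir.mkdir(parents=True, exist_ok=True)
    model_path = fold_dir / "model.json"
    state = model.to_state()
    state["version"] = config.version
    state["seed_used"] = model_seed
    with open(model_path, "w") as fh:
        json.dump(state, fh, indent=1, sort_keys=True)
    report.to_csv(fold_dir / "stats.csv")
    return FoldResult(o, i, predictions, report, model_path, penalties)


def run_experiment(config: ExperimentConfig, manifest, out_dir) -> List[FoldResult]:
    """Run the full nested-CV loop and write per-fold statistics.

    Every (outer, inner) pair gets its own preprocessing, per-fold
    penalty computation from the training partition only, model fit, and
    validation/test evaluation.  Fold failures are logged and the
    remaining folds proceed; an error is raised at the end if any fold
    failed, after all partial results have been written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = reference_models()
    if config.model_name not in registry:
        raise ConfigError(
            f"model {config.model_name!r} is not registered; known: {sorted(registry)}"
        )
    records = parse_manifest(manifest)
    data = {r.subject_id: _load_subject(r, config) for r in records}
    plan = make_nested_splits(
        [r.subject_id for r in records], config.k_outer, config.k_inner, config.seed
    )
    plan.to_csv(out_dir / "split_plan.csv")

    results: List[FoldResult] = []
    failures: List[str] = []
    log_lines = [f"# run seed={config.seed} version={config.version}"]
    combined = MetricReport()
    for o, i in plan.pairs():
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        try:
            result = _run_fold(o, i, plan.roles(o, i), data, config, registry, out_dir)
            results.append(result)
            combined.rows.extend(result.report.rows)
            log_lines.append(f"{stamp} fold ({o},{i}) ok")
        except Exception as exc:
            failures.append(f"fold ({o},{i}): {exc}")
            log_lines.append(f"{stamp} fold ({o},{i}) FAILED: {exc}")
            log_lines.append(traceback.format_exc())
    combined.to_csv(out_dir / "stats.csv")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    if failures:
        raise PatchflowError(
            f"{len(failures)} of {len(plan.pairs())} folds failed: {failures}"
        )
    return results


def _load_models(models_dir: Path) -> List:
    registry = reference_models()
    paths = sorted(Path(models_dir).rglob("model.json"))
    if not paths:
        raise PatchflowError(f"no fold model artifacts found under {models_dir}")
    models = []
    for p in paths:
        with open(p) as fh:
            state = json.load(fh)
        models.append(registry[state["model"]].from_state(state))
    return models


def run_inference(
    config: ExperimentConfig, manifest, models_dir, out_dir
) -> Tuple[Dict[str, object], Optional[MetricReport]]:
    """Ensemble inference with the saved fold models.

    Per-model predictions are fused per task (majority vote for
    segmentation/classification, mean for regression); metrics are
    computed only when the manifest carries targets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    models = _load_models(Path(models_dir))
    records = parse_manifest(manifest, require_target=False)
    have_targets = all(r.target is not None for r in records)

    fused: Dict[str, object] = {}
    report = MetricReport() if have_targets else None
    rows = []
    for record in records:
        image, target = _load_subject(record, config)
        sid = record.subject_id
        per_model = []
        for m_idx, model in enumerate(models):
            if config.task == "segmentation":
                pred = _segment_image(image, model, config)
            elif config.task == "classification":
                pred = _classify_image(image, model, config.patch_spec)
            else:
                pred = _regress_image(image, model, config.patch_spec)
            per_model.append(pred)
            per_dir = out_dir / "per_model" / f"model_{m_idx}"
            per_dir.mkdir(parents=True, exist_ok=True)
            if config.task == "segmentation":
                ext = ".nii.gz" if image.ndim_spatial == 3 else ".tif"
                write_image(pred, per_dir / f"{sid}_pred{ext}")
        fused_pred = ensemble_fuse(per_model, config.task)
        fused[sid] = fused_pred
        if config.task == "segmentation":
            ext = ".nii.gz" if image.ndim_spatial == 3 else ".tif"
            write_image(fused_pred, out_dir / f"{sid}_seg{ext}")
            if have_targets:
                for cls in [c for c in config.classes if c != 0]:
                    report.add("dice", dice(target, fused_pred, cls), 0, 0, sid, cls)
        else:
            rows.append({"SubjectID": sid, "prediction": fused_pred})
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "predictions.csv", index=False)
    if have_targets and config.task == "classification":
        gts = [int(r.target) for r in records]
        outs = [int(fused[r.subject_id]) for r in records]
        report.add("balanced_accuracy", multiclass_balanced_accuracy(gts, outs))
    elif have_targets and config.task == "regression":
        gts = [float(r.target) for r in records]
        outs = [float(fused[r.subject_id]) for r in records]
        report.add("mse", mse(gts, outs))
    if report is not None:
        report.to_csv(out_dir / "metrics.csv")
    return fused, report


# ---------------------------------------------------------------------------
# command-line interface


@click.group()
def main():
    """patchflow: config-driven patch-based imaging experiments."""


@main.command("run")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--train/--infer", "train_mode", default=True)
@click.option("--models-dir", type=click.Path(), default=None)
def cli_run(config_path, manifest, out_dir, train_mode, models_dir):
    """Train across the nested-CV folds, or run ensemble inference."""
    config = load_config(config_path)
    if train_mode:
        results = run_experiment(config, manifest, out_dir)
        click.echo(f"completed {len(results)} folds -> {out_dir}")
    else:
        if models_dir is None:
            raise click.UsageError("--infer requires --models-dir")
        fused, report = run_inference(config, manifest, models_dir, out_dir)
        click.echo(f"inferred {len(fused)} subjects -> {out_dir}")
        if report is not None:
            click.echo(report.to_frame().to_string(index=False))


@main.command("synth")
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--task", default="segmentation", type=click.Choice(_TASKS))
@click.option("--n-subjects", default=10, type=int)
@click.option("--shape", default="32,32,32")
@click.option("--n-classes", default=2, type=int)
@click.option("--noise-std", default=0.05, type=float)
@click.option("--seed", default=42, type=int)
def cli_synth(out_dir, task, n_subjects, shape, n_classes, noise_std, seed):
    """Generate a ready-to-run synthetic cohort with a default config."""
    shape = tuple(int(s) for s in shape.split(","))
    spec = SyntheticCohortSpec(
        n_subjects=n_subjects,
        task=task,
        ndim=len(shape),
        shape=shape,
        n_classes=n_classes,
        noise_std=noise_std,
        seed=seed,
    )
    manifest = make_manifest(spec, out_dir)
    default_model = {
        "segmentation": "threshold_segmenter",
        "classification": "majority_classifier",
        "regression": "mean_regressor",
    }[task]
    config = {
        "task": task,
        "model_name": default_model,
        "patch_size": [max(8, s // 2) for s in shape],
        "nested_training": {"testing": 2, "validation": 2},
        "classes": list(range(n_classes)),
        "seed": seed,
        "version": __version__,
    }
    config_path = Path(out_dir) / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    click.echo(f"wrote cohort: {manifest} and config: {config_path}")


@main.command("metrics")
@click.option("--gt", "gt_path", required=True, type=click.Path(exists=True))
@click.option("--pred", "pred_path", required=True, type=click.Path(exists=True))
@click.option("--classes", default="1")
def cli_metrics(gt_path, pred_path, classes):
    """Dice and HD95 between a ground-truth and a predicted mask."""
    gt = read_label(gt_path)
    pred = read_label(pred_path)
    for cls in (int(c) for c in classes.split(",")):
        d = dice(gt, pred, cls)
        h = hausdorff95(gt, pred, cls)
        click.echo(f"class {cls}: dice={d:.4f} hd95={h:.4f}")


if __name__ == "__main__":
    main()
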