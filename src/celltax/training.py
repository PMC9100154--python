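"""The 16-cell hyper-parameter grid trained under five-fold cross-validation.

The grid crosses four binary design choices — data augmentation on/off,
fine-tuning degree (all weights vs. first quarter frozen), optimizer (SGD
vs. AdaGrad) and learning-rate schedule (fixed 0.001 vs. exponential decay)
— giving 2**4 = 16 configurations per architecture.  Models are trained
with categorical cross-entropy; folds partition SOURCE IMAGES (all patches
of one micrograph share a fold), stratified by class, so no image leaks
between train and test of the same fold.
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from celltax.archs import ArchSpec, get_arch
from celltax.metrics import MetricsReport, compute_metrics
from celltax.model_factory import (
    FreezePolicy,
    OptimizerKind,
    ScheduleParams,
    build_classifier,
    make_optimizer,
)
from celltax.nn import cross_entropy
from celltax.patch_pipeline import (
    AugmentationParams,
    augment,
    normalize_array,
    resize_patch,
)
from celltax.segmentation import (
    CellBox,
    CellPatch,
    SegmentationParams,
    segment_image,
)

# placeholder box for patches whose provenance is tracked by the dataset keys
_DUMMY_BOX = CellBox(x=0, y=0, w=1, h=1)

__all__ = [
    "TrainConfig",
    "FoldResult",
    "ModelRecord",
    "enumerate_grid",
    "crossval_split",
    "build_patch_dataset",
    "train_one",
    "run_grid",
    "record_to_dict",
    "record_from_dict",
]


@dataclass(frozen=True)
class TrainConfig:
    """One cell of the 2x2x2x2 hyper-parameter grid.

    ``scheduler`` True means the exponential-decay schedule; False means a
    fixed rate of 0.001.
    """

    augmentation: bool
    fine_tuning: FreezePolicy
    optimizer: OptimizerKind
    scheduler: bool

    _LEVELS = {
        "augmentation": (False, True),
        "fine_tuning": (FreezePolicy.ALL_TRAINABLE,
                        FreezePolicy.FREEZE_FIRST_QUARTER),
        "optimizer": (OptimizerKind.SGD, OptimizerKind.ADAGRAD),
        "scheduler": (False, True),
    }

    @classmethod
    def factor_levels(cls, factor: str):
        try:
            return cls._LEVELS[factor]
        except KeyError:
            raise ValueError(f"unknown factor {factor!r}; "
                             f"expected one of {sorted(cls._LEVELS)}") from None

    def canonical_index(self) -> int:
        index = 0
        for factor in ("augmentation", "fine_tuning", "optimizer", "scheduler"):
            levels = self._LEVELS[factor]
            index = index * 2 + levels.index(getattr(self, factor))
        return index

    def with_value(self, factor: str, value) -> "TrainConfig":
        return replace(self, **{factor: value})

    def short_name(self) -> str:
        return (f"aug{int(self.augmentation)}"
                f"_frz{int(self.fine_tuning is FreezePolicy.FREEZE_FIRST_QUARTER)}"
                f"_{self.optimizer.value}"
                f"_sch{int(self.scheduler)}")


def enumerate_grid() -> list[TrainConfig]:
    """All 16 configurations in deterministic canonical order."""
    grid = [TrainConfig(aug, ft, opt, sch)
            for aug, ft, opt, sch in itertools.product(
                *(TrainConfig._LEVELS[f] for f in
                  ("augmentation", "fine_tuning", "optimizer", "scheduler")))]
    assert [c.canonical_index() for c in grid] == list(range(16))
    return grid


@dataclass
class FoldResult:
    """Test-fold outcome of one fitted model."""

    fold_index: int
    probability_matrix: np.ndarray   # N_test x 4
    true_labels: np.ndarray
    metrics: MetricsReport
    test_image_ids: tuple[str, ...] = ()


@dataclass
class ModelRecord:
    """One (architecture, configuration) training outcome over all folds."""

    arch: str
    config: TrainConfig
    fold_results: list[FoldResult]
    mean_accuracy: float

    @property
    def fold_signature(self) -> tuple[tuple[str, ...], ...]:
        return tuple(fr.test_image_ids for fr in self.fold_results)


# ---------------------------------------------------------------------------
# data handling


def crossval_split(manifest: dict, k: int = 5, seed: int = 0
                   ) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold partition of source images (not patches).

    Returns k (train_ids, test_ids) pairs over the manifest's image names;
    the test folds are pairwise disjoint and their union is the full set.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for entry in manifest["entries"]:
        by_class.setdefault(entry["class_id"], []).append(entry["image"])
    folds: list[list[str]] = [[] for _ in range(k)]
    for class_id in sorted(by_class):
        images = sorted(by_class[class_id])
        if len(images) < k:
            raise ValueError(
                f"class {class_id} has {len(images)} images; "
                f"need at least k={k} for stratified folds")
        rng.shuffle(images)
        for i, image in enumerate(images):
            folds[i % k].append(image)
    all_ids = sorted(itertools.chain.from_iterable(folds))
    return [(sorted(set(all_ids) - set(test)), sorted(test)) for test in folds]


def build_patch_dataset(manifest: dict,
                        params: SegmentationParams | None = None) -> dict:
    """Segment every manifest image into labelled patches.

    Returns ``{image_id: {"class_id": c, "patches": [uint8 arrays...]}}``.
    """
    root = Path(manifest["root"])
    dataset: dict[str, dict] = {}
    for entry in manifest["entries"]:
        image = iio.imread(root / entry["image"])
        patches = segment_image(image, params, source_image_id=entry["image"],
                                label=entry["class_id"])
        dataset[entry["image"]] = {
            "class_id": entry["class_id"],
            "patches": [p.pixels for p in patches],
        }
    return dataset


def _derived_seed(master_seed: int, arch: str, config_index: int,
                  fold: int) -> int:
    key = [master_seed, zlib.crc32(arch.encode()), config_index, fold]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31 - 1))


def _prepare_split(dataset: dict, image_ids: list[str], input_size: int):
    """Resize all patches of the listed images to the architecture's input.

    Returns the resized stack, labels, source image ids and the raw
    (pre-resize) patches, which augmentation operates on.
    """
    arrays, labels, sources, raw = [], [], [], []
    for image_id in image_ids:
        info = dataset[image_id]
        for pix in info["patches"]:
            patch = resize_patch(CellPatch(pixels=pix, box=_DUMMY_BOX), input_size)
            arrays.append(patch.pixels)
            labels.append(info["class_id"])
            sources.append(image_id)
            raw.append(pix)
    if not arrays:
        raise ValueError("no patches in split; check the segmentation stage")
    return np.stack(arrays), np.array(labels), sources, raw




def train_one(arch: ArchSpec | str, config: TrainConfig, dataset: dict,
              folds: list[tuple[list[str], list[str]]], epochs: int = 50,
              batch_size: int = 32, seed: int = 0) -> ModelRecord:
    """Fit one configuration on every fold and record test probabilities.

    Training uses categorical cross-entropy.  With augmentation on, each
    training patch is re-augmented every epoch (on the fly).  All
    randomness derives from ``(seed, arch, config, fold)``.
    """
    spec = get_arch(arch) if isinstance(arch, str) else arch
    if not spec.is_trainable_in_package:
        raise ValueError(
            f"{spec.name} has no in-package trainable weights; training runs "
            "use the smoke architecture family")
    aug_params = AugmentationParams(enabled=config.augmentation)
    schedule = ScheduleParams() if config.scheduler else 0.001
    fold_results: list[FoldResult] = []
    curves: list[dict] = []
    for fold_index, (train_ids, test_ids) in enumerate(folds):
        fold_seed = _derived_seed(seed, spec.name, config.canonical_index(),
                                  fold_index)
        rng = np.random.default_rng(fold_seed)
        model = build_classifier(spec, freeze=config.fine_tuning,
                                 seed=fold_seed)
        optimizer = make_optimizer(config.optimizer, schedule)
        x_train, y_train, _, raw_train = _prepare_split(dataset, train_ids,
                                                        spec.input_size)
        x_test, y_test, _, _ = _prepare_split(dataset, test_ids,
                                              spec.input_size)
        n = len(y_train)
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            epoch_correct = 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                batch = x_train[idx]
                if config.augmentation:
                    # augment the ORIGINAL crop, then resize to the network
                    # input, as in the acquisition-time pipeline
                    batch = np.stack([
                        resize_patch(
                            augment(CellPatch(pixels=raw_train[i],
                                              box=_DUMMY_BOX),
                                    aug_params,
                                    seed=int(rng.integers(2**31 - 1))),
                            spec.input_size).pixels
                        for i in idx])
                xb = normalize_array(batch, spec.normalization)
                logits = model.forward(xb)
                loss, dlogits = cross_entropy(logits, y_train[idx])
                model.backward(dlogits)
                optimizer.step(model)
                epoch_loss += loss * len(idx)
                epoch_correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
            curves.append({"fold": fold_index, "epoch": epoch,
                           "loss": epoch_loss / n,
                           "accuracy": 100.0 * epoch_correct / n})
        probs = model.predict_proba(
            normalize_array(x_test.astype(np.float64), spec.normalization))
        preds = probs.argmax(axis=1)
        fold_results.append(FoldResult(
            fold_index=fold_index,
            probability_matrix=probs,
            true_labels=y_test,
            metrics=compute_metrics(y_test, preds),
            test_image_ids=tuple(test_ids),
        ))
    mean_accuracy = float(np.mean([fr.metrics.accuracy for fr in fold_results]))
    record = ModelRecord(arch=spec.name, config=config,
                         fold_results=fold_results,
                         mean_accuracy=mean_accuracy)
    record.training_curves = curves
    return record


def run_grid(archs, dataset: dict, folds, configs=None, epochs: int = 50,
             batch_size: int = 32, seed: int = 0,
             out_dir: str | Path | None = None) -> list[ModelRecord]:
    """Train every requested (architecture, configuration) cell.

    With ``out_dir`` set, each finished record is persisted as JSON and a
    rerun resumes from the persisted records instead of retraining them.
    """
    configs = list(configs) if configs is not None else enumerate_grid()
    records: list[ModelRecord] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for arch in archs:
        spec = get_arch(arch) if isinstance(arch, str) else arch
        for config in configs:
            target = (out_path / f"{spec.name}_{config.short_name()}.json"
                      if out_path is not None else None)
            if target is not None and target.exists():
                with open(target) as fh:
                    records.append(record_from_dict(json.load(fh)))
                continue
            record = train_one(spec, config, dataset, folds, epochs=epochs,
                               batch_size=batch_size, seed=seed)
            records.append(record)
            if target is not None:
                with open(target, "w") as fh:
                    json.dump(record_to_dict(record), fh)
    return records


# ---------------------------------------------------------------------------
# persistence


def record_to_dict(record: ModelRecord) -> dict:
    return {
        "arch": record.arch,
        "config": {
            "augmentation": record.config.augmentation,
            "fine_tuning": record.config.fine_tuning.value,
            "optimizer": record.config.optimizer.value,
            "scheduler": record.config.scheduler,
        },
        "mean_accuracy": record.mean_accuracy,
        "folds": [
            {
                "fold_index": fr.fold_index,
                "probability_matrix": fr.probability_matrix.tolist(),
                "true_labels": fr.true_labels.tolist(),
                "test_image_ids": list(fr.test_image_ids),
                "metrics": {"accuracy": fr.metrics.accuracy,
                            "precision": fr.metrics.precision,
                            "recall": fr.metrics.recall,
                            "f1": fr.metrics.f1},
            }
            for fr in record.fold_results
        ],
    }


def record_from_dict(data: dict) -> ModelRecord:
    config = TrainConfig(
        augmentation=data["config"]["augmentation"],
        fine_tuning=FreezePolicy(data["config"]["fine_tuning"]),
        optimizer=OptimizerKind(data["config"]["optimizer"]),
        scheduler=data["config"]["scheduler"],
    )
    fold_results = []
    for fold in data["folds"]:
        probs = np.array(fold["probability_matrix"])
        labels = np.array(fold["true_labels"])
        fold_results.append(FoldResult(
            fold_index=fold["fold_index"],
            probability_matrix=probs,
            true_labels=labels,
            metrics=compute_metrics(labels, probs.argmax(axis=1)),
            test_image_ids=tuple(fold["test_image_ids"]),
        ))
    return ModelRecord(arch=data["arch"], config=config,
                       fold_results=fold_results,
                       mean_accuracy=data["mean_accuracy"])
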