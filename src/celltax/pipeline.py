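"""One-command orchestration: generate -> segment -> train -> ensemble ->
evaluate -> baselines, driven by a single YAML config.

Every stage records its artifacts and completion time in a run manifest
(``run_manifest.json`` in the run directory); re-running a completed stage
is a no-op, so interrupted runs resume where they stopped.  All randomness
flows from the single master seed in the config.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from celltax.archs import SMOKE_ARCHS, get_arch
from celltax.baselines import BaselineKind, run_baselines
from celltax.ensembles import build_multi_arch, build_single_arch, evaluate_ensemble
from celltax.metrics import compare_design_choice
from celltax.segmentation import SegmentationParams, segment_image
from celltax.synthetic import generate_dataset, load_manifest
from celltax.training import crossval_split, enumerate_grid, run_grid

__all__ = ["RunManifest", "run_pipeline", "default_smoke_config"]

log = logging.getLogger("celltax")

_version = "0.1.0"  # kept in sync with the package metadata

_STAGES = ("generate", "segment", "train", "ensembles", "evaluate", "baselines")

_SCHEMA = {
    "run_dir": str,
    "seed": int,
    "dataset": dict,
    "segmentation": dict,
    "training": dict,
    "ensembles": dict,
    "evaluation": dict,
    "baselines": dict,
}


@dataclass
class RunManifest:
    """Persisted state of one pipeline run."""

    config: dict
    master_seed: int
    run_dir: str
    tool_version: str = _version
    stages: dict = field(default_factory=dict)   # stage -> {completed_at, artifacts}

    def stage_complete(self, stage: str) -> bool:
        info = self.stages.get(stage)
        if not info:
            return False
        return all(Path(p).exists() for p in info.get("artifacts", []))

    def mark_complete(self, stage: str, artifacts: list[str]) -> None:
        self.stages[stage] = {"completed_at": time.time(),
                              "artifacts": [str(a) for a in artifacts]}
        self.save()

    @property
    def path(self) -> Path:
        return Path(self.run_dir) / "run_manifest.json"

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump({"config": self.config, "master_seed": self.master_seed,
                       "run_dir": self.run_dir, "tool_version": self.tool_version,
                       "stages": self.stages}, fh, indent=2)

    @classmethod
    def load(cls, run_dir: str | Path) -> "RunManifest":
        with open(Path(run_dir) / "run_manifest.json") as fh:
            data = json.load(fh)
        return cls(config=data["config"], master_seed=data["master_seed"],
                   run_dir=data["run_dir"], tool_version=data["tool_version"],
                   stages=data["stages"])


def default_smoke_config(run_dir: str, seed: int = 0) -> dict:
    """A CPU-scale configuration exercising every stage end to end."""
    return {
        "run_dir": run_dir,
        "seed": seed,
        "dataset": {"n_images_per_class": 8, "n_cells_range": [6, 12],
                    "n_debris_range": [2, 5]},
        "segmentation": {},
        "training": {"archs": ["micronet-a"], "n_configs": 4,
                     "epochs": 5, "batch_size": 32, "folds": 5},
        "ensembles": {"single_arch_k": [4], "multi_arch_k": []},
        "evaluation": {"factors": []},
        "baselines": {"kinds": ["lda", "knn"]},
    }


def _validate(config: dict) -> None:
    bad = [k for k in config if k not in _SCHEMA]
    bad += [k for k, t in _SCHEMA.items()
            if k in config and not isinstance(config[k], t)]
    missing = [k for k in ("run_dir", "seed") if k not in config]
    if bad or missing:
        raise ValueError(
            f"invalid config: offending keys {sorted(set(bad))}, "
            f"missing keys {missing}")


def run_pipeline(config: dict | str | Path) -> RunManifest:
    """Execute every stage of the taxonomy pipeline per the YAML config."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    _validate(config)
    run_dir = Path(config["run_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    if not logging.getLogger("celltax").handlers:
        logging.basicConfig(level=logging.INFO,
                            format="%(asctime)s %(name)s %(message)s")
    fh = logging.FileHandler(run_dir / "run.log")
    log.addHandler(fh)

    manifest_path = run_dir / "run_manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(run_dir)
    else:
        manifest = RunManifest(config=config, master_seed=seed,
                               run_dir=str(run_dir))
        manifest.save()

    try:
        _run_stages(config, manifest, run_dir, seed)
    finally:
        log.removeHandler(fh)
        fh.close()
    return manifest


def _run_stages(config: dict, manifest: RunManifest, run_dir: Path,
                seed: int) -> None:
    data_dir = run_dir / "data"
    patches_dir = run_dir / "patches"
    records_dir = run_dir / "records"
    results_dir = run_dir / "results"

    # -- generate ----------------------------------------------------------
    if not manifest.stage_complete("generate"):
        t0 = time.time()
        ds = config.get("dataset", {})
        generate_dataset(
            n_images_per_class=ds.get("n_images_per_class", 8),
            out_dir=data_dir,
            seed=seed,
            n_cells_range=tuple(ds.get("n_cells_range", (8, 16))),
            n_debris_range=tuple(ds.get("n_debris_range", (2, 6))),
        )
        log.info("stage=generate seed=%d elapsed=%.1fs", seed, time.time() - t0)
        manifest.mark_complete("generate", [data_dir / "manifest.json"])

    dataset_manifest = load_manifest(data_dir)

    # -- segment -----------------------------------------------------------
    seg_params = SegmentationParams(**config.get("segmentation", {}))
    if not manifest.stage_complete("segment"):
        t0 = time.time()
        patches_dir.mkdir(parents=True, exist_ok=True)
        for entry in dataset_manifest["entries"]:
            image = iio.imread(data_dir / entry["image"])
            patches = segment_image(image, seg_params,
                                    source_image_id=entry["image"],
                                    label=entry["class_id"])
            class_dir = patches_dir / f"class{entry['class_id']}"
            class_dir.mkdir(parents=True, exist_ok=True)
            stem = Path(entry["image"]).stem
            with open(patches_dir / f"{stem}_boxes.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["x", "y", "w", "h"])
                for i, patch in enumerate(patches):
                    writer.writerow([patch.box.x, patch.box.y,
                                     patch.box.w, patch.box.h])
                    iio.imwrite(class_dir / f"{stem}_p{i:03d}.png", patch.pixels)
        log.info("stage=segment elapsed=%.1fs", time.time() - t0)
        manifest.mark_complete(
            "segment",
            [patches_dir / f"{Path(e['image']).stem}_boxes.csv"
             for e in dataset_manifest["entries"]])

    # reload the patch dataset from the persisted crops
    dataset: dict[str, dict] = {}
    for entry in dataset_manifest["entries"]:
        stem = Path(entry["image"]).stem
        class_dir = patches_dir / f"class{entry['class_id']}"
        crops = sorted(class_dir.glob(f"{stem}_p*.png"))
        dataset[entry["image"]] = {
            "class_id": entry["class_id"],
            "patches": [iio.imread(p) for p in crops],
        }

    # -- train -------------------------------------------------------------
    training = config.get("training", {})
    k_folds = int(training.get("folds", 5))
    folds = crossval_split(dataset_manifest, k=k_folds, seed=seed)
    archs = [get_arch(a) for a in training.get("archs",
                                               sorted(SMOKE_ARCHS))]
    grid = enumerate_grid()
    n_configs = training.get("n_configs")
    configs = grid[:int(n_configs)] if n_configs else grid
    records = run_grid(
        archs, dataset, folds, configs=configs,
        epochs=int(training.get("epochs", 50)),
        batch_size=int(training.get("batch_size", 32)),
        seed=seed, out_dir=records_dir)
    if not manifest.stage_complete("train"):
        manifest.mark_complete(
            "train",
            [records_dir / f"{a.name}_{c.short_name()}.json"
             for a in archs for c in configs])

    results_dir.mkdir(parents=True, exist_ok=True)

    # -- ensembles ---------------------------------------------------------
    ens_cfg = config.get("ensembles", {})
    if not manifest.stage_complete("ensembles"):
        t0 = time.time()
        report: dict = {"single_arch": {}, "multi_arch": {}}
        by_arch: dict[str, list] = {}
        for record in records:
            by_arch.setdefault(record.arch, []).append(record)
        for k in ens_cfg.get("single_arch_k", []):
            for arch, arch_records in sorted(by_arch.items()):
                if len(arch_records) < k:
                    continue
                spec = build_single_arch(arch_records, k)
                result = evaluate_ensemble(spec)
                report["single_arch"][f"{arch}_top{k}"] = {
                    "mean_accuracy": result["mean_accuracy"],
                    "sd_accuracy": result["sd_accuracy"],
                    "members": [m.config.short_name() for m in spec.members],
                }
        for k in ens_cfg.get("multi_arch_k", []):
            spec = build_multi_arch(records, k)
            result = evaluate_ensemble(spec)
            report["multi_arch"][f"top{k}"] = {
                "mean_accuracy": result["mean_accuracy"],
                "sd_accuracy": result["sd_accuracy"],
                "members": [f"{m.arch}:{m.config.short_name()}"
                            for m in spec.members],
            }
        with open(results_dir / "ensembles.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("stage=ensembles elapsed=%.1fs", time.time() - t0)
        manifest.mark_complete("ensembles", [results_dir / "ensembles.json"])

    # -- evaluate ----------------------------------------------------------
    if not manifest.stage_complete("evaluate"):
        t0 = time.time()
        evaluation: dict = {
            "records": [{"arch": r.arch, "config": r.config.short_name(),
                         "mean_accuracy": r.mean_accuracy} for r in records],
            "comparisons": {},
        }
        for factor in config.get("evaluation", {}).get("factors", []):
            comparisons = compare_design_choice(records, factor)
            evaluation["comparisons"][factor] = {
                arch: {"statistic": c.statistic, "p_value": c.p_value,
                       "stars": c.stars, "n": c.n_used}
                for arch, c in comparisons.items()
            }
        with open(results_dir / "evaluation.json", "w") as fh:
            json.dump(evaluation, fh, indent=2)
        log.info("stage=evaluate elapsed=%.1fs", time.time() - t0)
        manifest.mark_complete("evaluate", [results_dir / "evaluation.json"])

    # -- baselines ---------------------------------------------------------
    if not manifest.stage_complete("baselines"):
        t0 = time.time()
        kinds = [BaselineKind(k) for k in
                 config.get("baselines", {}).get("kinds", [])]
        report = {}
        if kinds:
            results = run_baselines(dataset, folds, kinds=kinds, seed=seed)
            report = {kind: res["summary"] for kind, res in results.items()}
        with open(results_dir / "baselines.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("stage=baselines elapsed=%.1fs", time.time() - t0)
        manifest.mark_complete("baselines", [results_dir / "baselines.json"])
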