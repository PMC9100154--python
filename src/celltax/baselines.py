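"""Classic-ML comparison arm: HOG features + SVM / RF / LDA / kNN.

Patches are converted to grayscale, resized to 64x64 and described with a
histogram-of-oriented-gradients vector (9 orientation bins, 8x8-pixel
cells, 2x2-cell blocks, L2 block normalization with clipping; feature
length 7*7*2*2*9 = 1764).  The four classifiers are evaluated under the
same image-level five-fold partitions as the CNN arm, so the comparison
between arms is paired.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.feature import hog as _sk_hog
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from celltax.metrics import MetricsReport, compute_metrics
from celltax.segmentation import CellPatch, to_grayscale
from celltax.patch_pipeline import resize_patch

__all__ = ["HogParams", "BaselineKind", "extract_hog", "run_baselines"]


@dataclass(frozen=True)
class HogParams:
    resize: int = 64
    orientations: int = 9
    cell_size: int = 8
    block_size: int = 2
    block_norm: str = "L2-Hys"   # L2 with clipping

    @property
    def feature_length(self) -> int:
        blocks = self.resize // self.cell_size - (self.block_size - 1)
        return blocks * blocks * self.block_size**2 * self.orientations


class BaselineKind(Enum):
    SVM = "svm"
    RF = "rf"
    LDA = "lda"
    KNN = "knn"


def extract_hog(patch: CellPatch, params: HogParams = HogParams()) -> np.ndarray:
    """Deterministic HOG descriptor of one patch."""
    if patch.pixels.size == 0:
        raise ValueError("empty patch")
    resized = resize_patch(patch, params.resize)
    gray = to_grayscale(resized.pixels)
    return _sk_hog(gray,
                   orientations=params.orientations,
                   pixels_per_cell=(params.cell_size, params.cell_size),
                   cells_per_block=(params.block_size, params.block_size),
                   block_norm=params.block_norm,
                   feature_vector=True)


def _make_classifier(kind: BaselineKind, seed: int):
    # standard defaults: RBF-kernel SVM (C=1), 100-tree forest, default-
    # shrinkage LDA, k=5 neighbours
    if kind is BaselineKind.SVM:
        return SVC(C=1.0, kernel="rbf", random_state=seed)
    if kind is BaselineKind.RF:
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind is BaselineKind.LDA:
        return LinearDiscriminantAnalysis()
    if kind is BaselineKind.KNN:
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown baseline kind: {kind!r}")


def run_baselines(dataset: dict, folds, kinds=None, seed: int = 0,
                  params: HogParams = HogParams()) -> dict[str, dict]:
    """Cross-validate the classic-ML arm on pre-segmented patches.

    ``dataset`` and ``folds`` are the same structures the CNN arm consumes
    (see :func:`celltax.training.build_patch_dataset` and
    :func:`celltax.training.crossval_split`), keeping the fold partitions
    identical across arms.  Returns per-kind mean/sd of each metric plus
    the per-fold reports.
    """
    kinds = list(kinds) if kinds is not None else list(BaselineKind)
    features: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    from celltax.segmentation import CellBox
    dummy = CellBox(x=0, y=0, w=1, h=1)
    for image_id, info in dataset.items():
        feats = [extract_hog(CellPatch(pixels=p, box=dummy), params)
                 for p in info["patches"]]
        features[image_id] = (np.stack(feats) if feats
                              else np.empty((0, params.feature_length)))
        labels[image_id] = info["class_id"]

    def split_xy(ids):
        x = np.concatenate([features[i] for i in ids])
        y = np.concatenate([np.full(len(features[i]), labels[i]) for i in ids])
        return x, y

    results: dict[str, dict] = {}
    for kind in kinds:
        per_fold: list[MetricsReport] = []
        for train_ids, test_ids in folds:
            x_train, y_train = split_xy(train_ids)
            x_test, y_test = split_xy(test_ids)
            clf = _make_classifier(kind, seed)
            clf.fit(x_train, y_train)
            per_fold.append(compute_metrics(y_test, clf.predict(x_test)))
        summary = {}
        for metric in ("accuracy", "precision", "recall", "f1"):
            values = [getattr(m, metric) for m in per_fold]
            summary[metric] = {"mean": float(np.mean(values)),
                               "sd": float(np.std(values, ddof=1))}
        results[kind.value] = {"per_fold": per_fold, "summary": summary}
    return results
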