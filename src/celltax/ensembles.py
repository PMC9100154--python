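"""Soft-voting ensembles over trained model records.

Two selection strategies are provided: single-architecture ensembles take
the top-4/8/16 configurations of one backbone ranked by mean cross-validated
accuracy, and multi-architecture ensembles take the top-1/2/3 configurations
of every architecture (5, 10 and 15 members with five architectures).  The
vote is soft: member class-probability rows are summed element-wise and the
predicted label is the argmax of the sum, ties broken toward the lowest
class index.  Summing and averaging are order-equivalent, so duplicating
every member leaves predictions unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from celltax.metrics import MetricsReport, compute_metrics
from celltax.training import ModelRecord

__all__ = [
    "EnsembleStrategy",
    "EnsembleSpec",
    "rank_records",
    "build_single_arch",
    "build_multi_arch",
    "soft_vote",
    "evaluate_ensemble",
]

SINGLE_ARCH_SIZES = (4, 8, 16)
MULTI_ARCH_SIZES = (1, 2, 3)


class EnsembleStrategy(Enum):
    SINGLE_ARCH = "single_arch"
    MULTI_ARCH = "multi_arch"


@dataclass
class EnsembleSpec:
    """An ordered member list plus the soft-voting aggregation contract."""

    members: list[ModelRecord]
    strategy: EnsembleStrategy
    selection_k: int


def rank_records(records: list[ModelRecord]) -> list[ModelRecord]:
    """Descending by mean accuracy; ties broken by canonical config order."""
    if not records:
        raise ValueError("no records to rank")
    return sorted(records,
                  key=lambda r: (-r.mean_accuracy, r.config.canonical_index()))


def build_single_arch(records: list[ModelRecord], k: int) -> EnsembleSpec:
    """Top-k configurations of a single architecture (k in {4, 8, 16})."""
    if k not in SINGLE_ARCH_SIZES:
        raise ValueError(f"single-arch k must be one of {SINGLE_ARCH_SIZES}")
    arch_names = {r.arch for r in records}
    if len(arch_names) != 1:
        raise ValueError(f"records span several architectures: {arch_names}")
    if len(records) < k:
        raise ValueError(f"need at least {k} records, got {len(records)}")
    return EnsembleSpec(members=rank_records(records)[:k],
                        strategy=EnsembleStrategy.SINGLE_ARCH, selection_k=k)


def build_multi_arch(records: list[ModelRecord], k: int) -> EnsembleSpec:
    """Top-k configurations from every architecture present (k in {1, 2, 3}).

    With the five canonical architectures this yields 5, 10 or 15 members.
    """
    if k not in MULTI_ARCH_SIZES:
        raise ValueError(f"multi-arch k must be one of {MULTI_ARCH_SIZES}")
    by_arch: dict[str, list[ModelRecord]] = {}
    for record in records:
        by_arch.setdefault(record.arch, []).append(record)
    members: list[ModelRecord] = []
    for arch in sorted(by_arch):
        ranked = rank_records(by_arch[arch])
        if len(ranked) < k:
            raise ValueError(f"architecture {arch} has only {len(ranked)} "
                             f"records; need {k}")
        members.extend(ranked[:k])
    return EnsembleSpec(members=members,
                        strategy=EnsembleStrategy.MULTI_ARCH, selection_k=k)


def soft_vote(probability_matrices: list[np.ndarray]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Sum member probability matrices and argmax per row.

    Returns ``(labels, aggregated)`` where ``aggregated`` is the unnormalized
    element-wise sum.  Argmax ties break toward the lowest class index.
    """
    if not probability_matrices:
        raise ValueError("no probability matrices")
    shapes = {m.shape for m in map(np.asarray, probability_matrices)}
    if len(shapes) != 1:
        raise ValueError(f"member matrices disagree in shape: {shapes}")
    aggregated = np.sum([np.asarray(m, dtype=float)
                         for m in probability_matrices], axis=0)
    labels = aggregated.argmax(axis=1)  # np.argmax takes the first maximum
    return labels, aggregated


def evaluate_ensemble(spec: EnsembleSpec) -> dict:
    """Soft-vote the stored per-fold probabilities and score against truth.

    All members must share identical fold partitions.  Returns per-fold
    metric reports plus their mean and standard deviation (accuracy).
    """
    signatures = {m.fold_signature for m in spec.members}
    if len(signatures) != 1:
        raise ValueError("ensemble members were trained on different folds")
    n_folds = len(spec.members[0].fold_results)
    per_fold: list[MetricsReport] = []
    for fold in range(n_folds):
        matrices = [m.fold_results[fold].probability_matrix
                    for m in spec.members]
        truths = {tuple(m.fold_results[fold].true_labels) for m in spec.members}
        if len(truths) != 1:
            raise ValueError("ensemble members disagree on fold truth labels")
        labels, _ = soft_vote(matrices)
        per_fold.append(compute_metrics(
            spec.members[0].fold_results[fold].true_labels, labels))
    accuracies = [m.accuracy for m in per_fold]
    return {
        "per_fold": per_fold,
        "mean_accuracy": float(np.mean(accuracies)),
        "sd_accuracy": float(np.std(accuracies, ddof=1)) if n_folds > 1 else 0.0,
    }
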