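"""Soft-voting ensembles and paired Wilcoxon comparisons.

Trains one configuration per small architecture, builds the heterogeneous
(multi-architecture) top-1 soft-voting ensemble, and compares ensemble and
member accuracies fold by fold with the Wilcoxon signed-rank test.
"""

import tempfile

import numpy as np

from celltax.archs import SMOKE_ARCHS, get_arch
from celltax.ensembles import build_multi_arch, evaluate_ensemble
from celltax.metrics import wilcoxon_signed_rank
from celltax.synthetic import generate_dataset
from celltax.training import (
    build_patch_dataset,
    crossval_split,
    enumerate_grid,
    train_one,
)

config = enumerate_grid()[2]   # no augmentation, all weights, AdaGrad, fixed lr

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_dataset(8, tmp, seed=1, n_cells_range=(6, 12))
    dataset = build_patch_dataset(manifest)
    folds = crossval_split(manifest, k=5, seed=1)

    members = []
    for name in sorted(SMOKE_ARCHS):
        record = train_one(get_arch(name), config, dataset, folds,
                           epochs=5, batch_size=8, seed=1)
        members.append(record)
        print(f"{name}: mean accuracy {record.mean_accuracy:.1f}%")

    ensemble = evaluate_ensemble(build_multi_arch(members, 1))
    member_mean = np.mean([m.mean_accuracy for m in members])
    print(f"\nmulti-arch top-1 ensemble ({len(members)} members): "
          f"{ensemble['mean_accuracy']:.1f}% "
          f"vs member mean {member_mean:.1f}%")

    ens_folds = [m.accuracy for m in ensemble["per_fold"]]
    best = max(members, key=lambda m: m.mean_accuracy)
    best_folds = [fr.metrics.accuracy for fr in best.fold_results]
    try:
        cmp = wilcoxon_signed_rank(ens_folds, best_folds)
        print(f"ensemble vs best member, 5 paired folds: W={cmp.statistic}, "
              f"p={cmp.p_value:.3f} {cmp.stars or '(not significant)'}")
    except ValueError as exc:
        print(f"paired test degenerate: {exc}")
    print("soft voting sums member class probabilities per patch and takes "
          "the argmax; diverse members make the sum more reliable than the "
          "average member")
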