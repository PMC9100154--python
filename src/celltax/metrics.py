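"""Support-weighted classification metrics and paired Wilcoxon comparisons.

Metrics follow the convention of reporting accuracy, precision, recall and
F1 as percentages with support-weighted multiclass averaging (under which
weighted recall equals accuracy identically).  Model variants are compared
with the two-sided Wilcoxon signed-rank test on paired accuracies: zero
differences are dropped, tied absolute differences receive mid-ranks, the
null distribution is exact for n <= 25 pairs and a normal approximation
with tie and continuity corrections is used above.  Significance is
annotated with the usual star convention: * (p < 0.05), ** (p < 0.01),
*** (p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
)

__all__ = [
    "MetricsReport",
    "PairedComparison",
    "DegenerateComparisonError",
    "compute_metrics",
    "confusion_matrix",
    "wilcoxon_signed_rank",
    "stars_for_p",
    "compare_design_choice",
]

N_CLASSES = 4
_LABELS = list(range(N_CLASSES))


class DegenerateComparisonError(ValueError):
    """All paired differences are zero; no signed-rank test can be performed."""


@dataclass
class MetricsReport:
    """Percent-scale metric suite with a per-class breakdown."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict = field(default_factory=dict)
    averaging: str = "weighted"

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def compute_metrics(true_labels, predicted_labels) -> MetricsReport:
    """Accuracy plus support-weighted precision/recall/F1, all in percent."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label lists must have equal length")
    _check_labels(y_true, y_pred)
    acc = accuracy_score(y_true, y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=_LABELS, average="weighted", zero_division=0)
    p_c, r_c, f_c, s_c = precision_recall_fscore_support(
        y_true, y_pred, labels=_LABELS, average=None, zero_division=0)
    per_class = {
        "precision": (100 * p_c).tolist(),
        "recall": (100 * r_c).tolist(),
        "f1": (100 * f_c).tolist(),
        "support": s_c.tolist(),
    }
    return MetricsReport(accuracy=100 * acc, precision=100 * prec,
                         recall=100 * rec, f1=100 * f1, per_class=per_class)


def _check_labels(*arrays) -> None:
    for arr in arrays:
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """4x4 count matrix; entry (i, j) = true class i predicted as class j."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label lists must have equal length")
    _check_labels(y_true, y_pred)
    return _sk_confusion(y_true, y_pred, labels=_LABELS)


def stars_for_p(p: float) -> str:
    """Map a p-value to the significance-star convention."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class PairedComparison:
    """Result of one two-sided Wilcoxon signed-rank comparison."""

    sample_a: list
    sample_b: list
    statistic: float
    p_value: float
    stars: str
    n_used: int


def _exact_two_sided_p(ranks: np.ndarray, w_min: float) -> float:
    """Exact p over all sign assignments, supporting tied mid-ranks.

    Mid-ranks are half-integers, so doubling them gives integers and the
    null distribution of 2*W+ can be built by dynamic programming.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    n_assign = 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_min))
    cdf = counts[:w2 + 1].sum() / n_assign
    return min(1.0, 2.0 * cdf)


def wilcoxon_signed_rank(a, b) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    The statistic is ``W = min(W+, W-)``, the smaller of the positive and
    negative rank sums after dropping zero differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateComparisonError("all paired differences are zero")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        p = _exact_two_sided_p(ranks, w)
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w - mean + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * norm.cdf(z))
    return PairedComparison(sample_a=a.tolist(), sample_b=b.tolist(),
                            statistic=w, p_value=p, stars=stars_for_p(p),
                            n_used=n)


# ---------------------------------------------------------------------------
# design-choice comparisons over a trained grid

def compare_design_choice(records, factor: str) -> dict[str, PairedComparison]:
    """Per-architecture paired comparison of one hyper-parameter factor.

    For each architecture the 8 configurations with the factor at its first
    level are paired with the 8 matched configurations (all other factors
    equal) at the second level, and the fold-level accuracies of the matched
    pairs are compared with the Wilcoxon signed-rank test.  ``factor`` is
    one of "augmentation", "fine_tuning", "optimizer", "scheduler".
    """
    from celltax.training import TrainConfig  # local to avoid a cycle

    attr = factor
    level_a, level_b = TrainConfig.factor_levels(factor)

    by_arch: dict[str, list] = {}
    for record in records:
        by_arch.setdefault(record.arch, []).append(record)

    out: dict[str, PairedComparison] = {}
    for arch, arch_records in sorted(by_arch.items()):
        index = {rec.config: rec for rec in arch_records}
        a_vals: list[float] = []
        b_vals: list[float] = []
        seen = set()
        for config, rec in sorted(index.items(),
                                  key=lambda kv: kv[0].canonical_index()):
            if getattr(config, attr) != level_a:
                continue
            partner_cfg = config.with_value(attr, level_b)
            partner = index.get(partner_cfg)
            if partner is None:
                raise ValueError(
                    f"incomplete grid for {arch}: missing match for {config}")
            seen.add(config)
            a_vals.extend(fr.metrics.accuracy for fr in rec.fold_results)
            b_vals.extend(fr.metrics.accuracy for fr in partner.fold_results)
        if not a_vals:
            raise ValueError(f"no configs at level {level_a!r} for {arch}")
        out[arch] = wilcoxon_signed_rank(a_vals, b_vals)
    return out
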