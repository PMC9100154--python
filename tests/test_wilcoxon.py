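"""Wilcoxon signed-rank test: exact null, approximation, star convention."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from celltax.metrics import (
    DegenerateComparisonError,
    compare_design_choice,
    stars_for_p,
    wilcoxon_signed_rank,
)
from celltax.model_factory import FreezePolicy, OptimizerKind
from celltax.training import FoldResult, ModelRecord, enumerate_grid
from celltax.metrics import compute_metrics


def _bruteforce_two_sided_p(d: np.ndarray) -> tuple[float, float]:
    """Independent oracle: enumerate all 2^n sign assignments."""
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-12:
            count += 1
    return w_obs, min(1.0, 2.0 * count / 2**n)


def test_all_zero_differences_is_degenerate():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    with pytest.raises(DegenerateComparisonError):
        wilcoxon_signed_rank(a, a)


def test_six_pairs_single_sign_exact_case():
    a = np.arange(1.0, 7.0)
    b = a + 10.0
    result = wilcoxon_signed_rank(a, b)
    assert result.statistic == 0.0
    assert result.p_value == pytest.approx(2 / 64)   # 0.03125
    assert result.stars == "*"


@pytest.mark.parametrize("p,expected", [
    (0.0005, "***"), (0.001, "**"), (0.009, "**"), (0.02, "*"),
    (0.049, "*"), (0.05, ""), (0.2, ""),
])
def test_star_threshold_mapping(p, expected):
    assert stars_for_p(p) == expected


@pytest.mark.parametrize("n", [5, 6, 8, 10, 12])
def test_exact_p_matches_full_enumeration(n):
    rng = np.random.default_rng(n)
    for trial in range(4):
        a = rng.integers(0, 6, size=n).astype(float)   # integer ties likely
        b = rng.integers(0, 6, size=n).astype(float)
        d = a - b
        if not np.any(d):
            continue
        w_oracle, p_oracle = _bruteforce_two_sided_p(d)
        result = wilcoxon_signed_rank(a, b)
        assert result.statistic == pytest.approx(w_oracle)
        assert result.p_value == pytest.approx(p_oracle, abs=1e-12)


def test_matches_scipy_exact_mode_without_ties():
    rng = np.random.default_rng(77)
    a = rng.normal(size=12)
    b = rng.normal(size=12)
    ours = wilcoxon_signed_rank(a, b)
    ref = scipy_wilcoxon(a, b, alternative="two-sided", mode="exact")
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_large_n_normal_approximation_is_sane():
    rng = np.random.default_rng(5)
    a = rng.normal(size=40)
    b = a + rng.normal(scale=0.5, size=40) + 0.3
    ours = wilcoxon_signed_rank(a, b)
    ref = scipy_wilcoxon(a, b, alternative="two-sided", mode="approx",
                         correction=True)
    assert ours.p_value == pytest.approx(ref.pvalue, rel=0.05)
    assert 0.0 < ours.p_value < 1.0


# ---------------------------------------------------------------------------
# design-choice comparisons on a synthetic full grid


def _grid_records(arch: str, accuracy_fn, n_folds: int = 5):
    """A full 16-config grid with accuracies prescribed per config/fold."""
    records = []
    for config in enumerate_grid():
        fold_results = []
        for fold in range(n_folds):
            acc = accuracy_fn(config, fold)
            n = 100
            correct = int(round(n * acc / 100))
            labels = np.zeros(n, dtype=int)
            preds = np.concatenate([np.zeros(correct, dtype=int),
                                    np.ones(n - correct, dtype=int)])
            probs = np.eye(4)[preds]
            fold_results.append(FoldResult(
                fold_index=fold, probability_matrix=probs,
                true_labels=labels,
                metrics=compute_metrics(labels, preds),
                test_image_ids=(f"f{fold}",)))
        records.append(ModelRecord(
            arch=arch, config=config, fold_results=fold_results,
            mean_accuracy=float(np.mean([fr.metrics.accuracy
                                         for fr in fold_results]))))
    return records


def test_uniformly_dominant_augmentation_reaches_floor_p():
    """When augmented configs dominate in every pair, the comparison hits the
    smallest attainable p for 40 equal-sign pairs."""
    rng = np.random.default_rng(0)
    jitter = {}

    def accuracy(config, fold):
        key = (config.canonical_index() % 8, fold)
        jitter.setdefault(key, rng.uniform(0, 3))
        return 70 + 10 * config.augmentation + jitter[key] + 0.5 * fold

    records = _grid_records("archA", accuracy)
    result = compare_design_choice(records, "augmentation")["archA"]
    assert result.stars == "***"
    assert result.n_used == 40


def test_null_factor_shows_no_stars():
    def accuracy(config, fold):
        # scheduler has no effect; other factors shift accuracy
        return (60 + 5 * config.augmentation
                + 3 * (config.optimizer is OptimizerKind.ADAGRAD)
                + 2 * (config.fine_tuning is FreezePolicy.ALL_TRAINABLE)
                + fold)

    records = _grid_records("archB", accuracy)
    with pytest.raises(DegenerateComparisonError):
        # identical paired accuracies: the test itself is degenerate
        compare_design_choice(records, "scheduler")


def test_incomplete_grid_rejected():
    records = _grid_records("archC", lambda c, f: 70 + c.canonical_index())
    with pytest.raises(ValueError):
        compare_design_choice(records[:-1], "optimizer")


def test_each_factor_uses_eight_matched_pairs_per_fold():
    records = _grid_records("archD",
                            lambda c, f: 60 + c.canonical_index() + f)
    for factor in ("augmentation", "fine_tuning", "optimizer", "scheduler"):
        result = compare_design_choice(records, factor)["archD"]
        assert result.n_used == 8 * 5   # 8 matched pairs x 5 folds
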