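"""Ranking, ensemble construction and the soft-voting oracle."""

import itertools

import numpy as np
import pytest

from celltax.ensembles import (
    build_multi_arch,
    build_single_arch,
    evaluate_ensemble,
    rank_records,
    soft_vote,
)
from celltax.metrics import compute_metrics
from celltax.model_factory import FreezePolicy, OptimizerKind
from celltax.training import FoldResult, ModelRecord, enumerate_grid

_GRID = enumerate_grid()


def _fake_record(arch: str, config_index: int, accuracy: float,
                 seed: int = 0, n_folds: int = 2, n_samples: int = 6,
                 fold_tag: str = "shared") -> ModelRecord:
    """A synthetic ModelRecord with random (valid) probability matrices."""
    rng = np.random.default_rng(seed)
    fold_results = []
    for fold in range(n_folds):
        raw = rng.random((n_samples, 4))
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 4, size=n_samples)
        fold_results.append(FoldResult(
            fold_index=fold,
            probability_matrix=probs,
            true_labels=labels,
            metrics=compute_metrics(labels, probs.argmax(axis=1)),
            test_image_ids=(f"{fold_tag}_fold{fold}",),
        ))
    return ModelRecord(arch=arch, config=_GRID[config_index],
                       fold_results=fold_results, mean_accuracy=accuracy)


class TestRanking:
    def test_descending_by_accuracy(self):
        records = [_fake_record("a", i, acc)
                   for i, acc in enumerate([90.0, 95.0, 92.0])]
        assert [r.mean_accuracy for r in rank_records(records)] == [95, 92, 90]

    def test_ties_break_by_canonical_config_order(self):
        records = [_fake_record("a", i, 90.0) for i in (3, 0, 2)]
        ranked = rank_records(records)
        assert [r.config.canonical_index() for r in ranked] == [0, 2, 3]

    def test_rank_is_idempotent(self):
        records = [_fake_record("a", i, acc)
                   for i, acc in enumerate([88.0, 99.0, 91.0, 91.0])]
        once = rank_records(records)
        assert rank_records(once) == once


class TestBuilders:
    def test_single_arch_top_k(self):
        records = [_fake_record("a", i, 80.0 + i) for i in range(16)]
        spec = build_single_arch(records, 4)
        assert len(spec.members) == 4
        assert {m.arch for m in spec.members} == {"a"}
        assert [m.mean_accuracy for m in spec.members] == [95, 94, 93, 92]

    def test_single_arch_full_set_when_k_16(self):
        records = [_fake_record("a", i, 80.0 + i) for i in range(16)]
        assert len(build_single_arch(records, 16).members) == 16

    def test_single_arch_k_validation(self):
        records = [_fake_record("a", i, 80.0) for i in range(16)]
        with pytest.raises(ValueError):
            build_single_arch(records, 5)

    def test_fifteen_single_arch_pipelines_across_five_archs(self):
        archs = ["a1", "a2", "a3", "a4", "a5"]
        pipelines = [
            build_single_arch([_fake_record(a, i, 80.0 + i)
                               for i in range(16)], k)
            for a in archs for k in (4, 8, 16)
        ]
        assert len(pipelines) == 15

    @pytest.mark.parametrize("k,expected", [(1, 5), (2, 10), (3, 15)])
    def test_multi_arch_member_counts(self, k, expected):
        records = [_fake_record(arch, i, 80.0 + i)
                   for arch in ("a1", "a2", "a3", "a4", "a5")
                   for i in range(3)]
        spec = build_multi_arch(records, k)
        assert len(spec.members) == expected
        per_arch = {a: sum(m.arch == a for m in spec.members)
                    for a in ("a1", "a2", "a3", "a4", "a5")}
        assert set(per_arch.values()) == {k}

    def test_multi_arch_missing_architecture_records(self):
        records = [_fake_record("a1", i, 80.0) for i in range(2)]
        records += [_fake_record("a2", 0, 80.0)]
        with pytest.raises(ValueError):
            build_multi_arch(records, 2)


class TestSoftVote:
    def test_single_member_identity(self):
        rng = np.random.default_rng(0)
        raw = rng.random((7, 4))
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels, agg = soft_vote([probs])
        assert np.array_equal(labels, probs.argmax(axis=1))
        assert np.allclose(agg, probs)

    def test_hand_computed_two_member_example(self):
        a = np.array([[0.6, 0.2, 0.1, 0.1]])
        b = np.array([[0.2, 0.5, 0.2, 0.1]])
        labels, agg = soft_vote([a, b])
        assert np.allclose(agg, [[0.8, 0.7, 0.3, 0.2]])
        assert labels.tolist() == [0]

    def test_ties_break_to_lowest_class_index(self):
        a = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.25, 0.5, 0.25]])
        b = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.75, 0.25, 0.0]])
        labels, _ = soft_vote([a, b])
        assert labels.tolist() == [0, 1]

    def test_agrees_with_bruteforce_enumeration(self):
        """Every <=3-member ensemble over a 5-sample toy set matches an
        exhaustive per-sample, per-class summation oracle."""
        rng = np.random.default_rng(1)
        members = []
        for _ in range(4):
            raw = rng.random((5, 4))
            members.append(raw / raw.sum(axis=1, keepdims=True))
        for size in (1, 2, 3):
            for subset in itertools.combinations(range(4), size):
                chosen = [members[i] for i in subset]
                labels, _ = soft_vote(chosen)
                for s in range(5):
                    sums = [sum(m[s, c] for m in chosen) for c in range(4)]
                    best = max(range(4), key=lambda c: (sums[c], -c))
                    assert labels[s] == best

    def test_duplication_invariance(self):
        rng = np.random.default_rng(2)
        members = [rng.random((6, 4)) for _ in range(3)]
        labels, _ = soft_vote(members)
        doubled, _ = soft_vote(members + members)
        assert np.array_equal(labels, doubled)

    def test_sum_equals_mean_aggregation(self):
        rng = np.random.default_rng(3)
        members = [rng.random((6, 4)) for _ in range(3)]
        labels, agg = soft_vote(members)
        assert np.array_equal(labels, (agg / len(members)).argmax(axis=1))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_vote([np.zeros((3, 4)), np.zeros((2, 4))])


class TestEvaluateEnsemble:
    def test_duplicated_member_matches_single_record(self):
        record = _fake_record("a", 0, 80.0, seed=5)
        spec = build_single_arch([record] * 16, 4)
        result = evaluate_ensemble(spec)
        single_accs = [fr.metrics.accuracy for fr in record.fold_results]
        ensemble_accs = [m.accuracy for m in result["per_fold"]]
        assert ensemble_accs == pytest.approx(single_accs)
        assert result["mean_accuracy"] == pytest.approx(np.mean(single_accs))
        assert len(result["per_fold"]) == len(record.fold_results)

    def test_mismatched_folds_rejected(self):
        from celltax.ensembles import EnsembleSpec, EnsembleStrategy

        a = _fake_record("a", 0, 80.0, fold_tag="x")
        b = _fake_record("a", 1, 82.0, fold_tag="y")
        spec = EnsembleSpec(members=[a, b],
                            strategy=EnsembleStrategy.SINGLE_ARCH,
                            selection_k=4)
        with pytest.raises(ValueError):
            evaluate_ensemble(spec)
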