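"""Parameter accounting, freeze policies, schedule and optimizers."""

import numpy as np
import pytest

from celltax.archs import CANONICAL_ARCHS, SMOKE_ARCHS, get_arch
from celltax.backbone_accounting import (
    BACKBONE_NAMES,
    FEATURE_DIM,
    backbone_layers,
    head_params,
    trainable_parameters,
)
from celltax.model_factory import (
    FreezePolicy,
    OptimizerKind,
    ScheduleParams,
    build_classifier,
    count_trainable,
    learning_rate,
    make_optimizer,
)
from celltax.nn import SmallCNN


class TestAccounting:
    def test_head_is_dense_layer_arithmetic(self):
        for name in BACKBONE_NAMES:
            assert head_params(name) == FEATURE_DIM[name] * 4 + 4

    def test_freeze_strictly_reduces_trainable_count(self):
        for name in BACKBONE_NAMES:
            assert trainable_parameters(name, True) < trainable_parameters(name)

    def test_frozen_delta_equals_prefix_sum(self):
        from celltax.backbone_accounting import FREEZE_PREFIX

        for name in BACKBONE_NAMES:
            layers = backbone_layers(name)
            prefix = sum(l.trainable for l in layers[:FREEZE_PREFIX[name]])
            delta = trainable_parameters(name) - trainable_parameters(name, True)
            assert delta == prefix

    def test_moving_statistics_never_trainable(self):
        # every batch-norm layer carries 2 moving tensors per channel
        layers = backbone_layers("ResNet50")
        bn_layers = [l for l in layers if l.name.endswith("bn")]
        assert bn_layers and all(l.non_trainable == l.trainable for l in bn_layers)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            backbone_layers("VGG16")

    def test_accounting_model_summary(self):
        model = build_classifier("DenseNet121", FreezePolicy.ALL_TRAINABLE)
        summary = model.summary()
        assert summary["trainable_parameters"] == count_trainable(model)
        assert summary["head_parameters"] == 1024 * 4 + 4


class TestSchedule:
    def test_closed_form_values(self):
        assert learning_rate(0) == pytest.approx(0.001)
        assert learning_rate(10_000) == pytest.approx(0.00096)
        assert learning_rate(20_000) == pytest.approx(0.0009216)

    @pytest.mark.parametrize("t", [0, 137, 5_000, 123_456])
    def test_decay_ratio_per_decay_step(self, t):
        assert (learning_rate(t + 10_000) / learning_rate(t)
                == pytest.approx(0.96))

    def test_strictly_decreasing_and_positive(self):
        ts = np.linspace(0, 200_000, 50)
        rates = [learning_rate(t) for t in ts]
        assert all(r > 0 for r in rates)
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            learning_rate(-1)


class _OneParamModel:
    """Minimal stand-in exposing the optimizer stepping contract."""

    def __init__(self, theta, grad):
        self.theta = np.array(theta, dtype=float)
        self.grad = np.array(grad, dtype=float)

    def trainable_params_and_grads(self):
        yield self.theta, self.grad


class TestOptimizers:
    def test_sgd_single_step(self):
        model = _OneParamModel([1.0, -2.0], [0.5, 0.25])
        make_optimizer(OptimizerKind.SGD, 0.001).step(model)
        assert np.allclose(model.theta, [1.0 - 0.001 * 0.5,
                                         -2.0 - 0.001 * 0.25])

    def test_adagrad_two_step_hand_trace(self):
        eps = 1e-7
        g1, g2 = 0.4, -0.3
        model = _OneParamModel([0.0], [g1])
        opt = make_optimizer(OptimizerKind.ADAGRAD, 0.001)
        opt.step(model)
        expected = -0.001 * g1 / (np.sqrt(g1**2) + eps)
        assert model.theta[0] == pytest.approx(expected, rel=1e-9)
        # first step is ~ lr * sign(g) for g >> eps
        assert model.theta[0] == pytest.approx(-0.001, rel=1e-5)
        model.grad[0] = g2
        opt.step(model)
        expected += -0.001 * g2 / (np.sqrt(g1**2 + g2**2) + eps)
        assert model.theta[0] == pytest.approx(expected, rel=1e-9)

    def test_schedule_attached_to_optimizer(self):
        opt = make_optimizer(OptimizerKind.SGD, ScheduleParams())
        assert opt.current_rate() == pytest.approx(0.001)
        opt.t = 10_000
        assert opt.current_rate() == pytest.approx(0.00096)


class TestBuildClassifier:
    def test_canonical_build_returns_accounting_handle(self):
        for name in CANONICAL_ARCHS:
            model = build_classifier(name)
            assert count_trainable(model) > 0

    @pytest.mark.parametrize("name", sorted(SMOKE_ARCHS))
    def test_smoke_output_is_probability_simplex(self, name):
        model = build_classifier(name, seed=1)
        assert isinstance(model, SmallCNN)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 32, 32, 3))
        probs = model.predict_proba(x)
        assert probs.shape == (3, 4)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_smoke_freeze_reduces_trainable_count(self):
        full = build_classifier("micronet-a", FreezePolicy.ALL_TRAINABLE)
        frozen = build_classifier("micronet-a",
                                  FreezePolicy.FREEZE_FIRST_QUARTER)
        assert frozen.count_trainable() < full.count_trainable()

    def test_smoke_head_always_trainable(self):
        frozen = build_classifier("micronet-b",
                                  FreezePolicy.FREEZE_FIRST_QUARTER)
        assert frozen.head.trainable

    def test_smoke_pretrained_rejected(self):
        with pytest.raises(ValueError):
            build_classifier("micronet-a", pretrained=True)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            get_arch("AlexNet")
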