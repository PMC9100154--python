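"""Classifier construction, fine-tuning policies, optimizers and the
learning-rate schedule.

Two fine-tuning regimes are supported: training every weight, or freezing
the first ~25% of the backbone's layers and training the rest (the head is
always trainable).  Optimization is plain SGD or AdaGrad, at a fixed rate
of 0.001 or under the exponential-decay schedule

    eta(t) = eta(0) * d ** (t / r)

with initial rate eta(0) = 0.001, decay rate d = 0.96 and decay step
r = 10,000, evaluated continuously (non-staircase) in the step index t.

For the five canonical backbones this module provides parameter-accounting
model handles (exact trainable counts per policy); trainable classifiers
are provided for the smoke family, which shares every contract but fits on
a CPU.  Pretrained canonical weights are not shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from celltax import backbone_accounting as _acct
from celltax.archs import ArchSpec, get_arch
from celltax.nn import AdaGrad, SGD, SmallCNN

__all__ = [
    "FreezePolicy",
    "OptimizerKind",
    "ScheduleParams",
    "AccountingModel",
    "build_classifier",
    "count_trainable",
    "learning_rate",
    "make_optimizer",
]


class FreezePolicy(Enum):
    ALL_TRAINABLE = "all_trainable"
    FREEZE_FIRST_QUARTER = "freeze_first_quarter"


class OptimizerKind(Enum):
    SGD = "sgd"
    ADAGRAD = "adagrad"


@dataclass(frozen=True)
class ScheduleParams:
    """Exponential-decay schedule constants."""

    initial_rate: float = 0.001
    decay_rate: float = 0.96
    decay_steps: int = 10_000


def learning_rate(t: float, params: ScheduleParams = ScheduleParams()) -> float:
    """Continuous exponential decay: ``eta(0) * decay_rate ** (t / decay_steps)``."""
    if t < 0:
        raise ValueError("step index must be >= 0")
    return params.initial_rate * params.decay_rate ** (t / params.decay_steps)


@dataclass(frozen=True)
class AccountingModel:
    """Parameter-accounting handle for a canonical backbone + 4-way head.

    Supports exact trainable-parameter accounting under both fine-tuning
    policies; it carries no weights (pretrained canonical weights are not
    shipped), so it cannot predict.
    """

    arch: ArchSpec
    freeze: FreezePolicy
    pretrained: bool

    def count_trainable(self) -> int:
        return _acct.trainable_parameters(
            self.arch.name,
            freeze_first_quarter=self.freeze is FreezePolicy.FREEZE_FIRST_QUARTER,
        )

    def summary(self) -> dict:
        return {
            "architecture": self.arch.name,
            "input_size": self.arch.input_size,
            "feature_dim": self.arch.feature_dim,
            "freeze_policy": self.freeze.value,
            "trainable_parameters": self.count_trainable(),
            "head_parameters": _acct.head_params(self.arch.name),
        }


def build_classifier(arch: ArchSpec | str,
                     freeze: FreezePolicy = FreezePolicy.ALL_TRAINABLE,
                     pretrained: bool = False,
                     seed: int = 0):
    """Build a 4-way classifier for one architecture.

    Smoke-family architectures return a trainable :class:`~celltax.nn.SmallCNN`
    (randomly initialized; ``pretrained`` has no published weights to load and
    must be False).  Canonical architectures return an
    :class:`AccountingModel`.
    """
    spec = get_arch(arch) if isinstance(arch, str) else arch
    if spec.family == "smoke":
        if pretrained:
            raise ValueError("smoke architectures have no pretrained weights")
        return SmallCNN(
            spec.conv_widths,
            n_classes=4,
            seed=seed,
            freeze_first_quarter=freeze is FreezePolicy.FREEZE_FIRST_QUARTER,
        )
    return AccountingModel(arch=spec, freeze=freeze, pretrained=pretrained)


def count_trainable(model) -> int:
    """Trainable parameter count of any model handle built by this module."""
    return model.count_trainable()


def make_optimizer(kind: OptimizerKind,
                   schedule: ScheduleParams | float = 0.001):
    """Create an optimizer consuming a fixed rate or the decay schedule."""
    if isinstance(schedule, ScheduleParams):
        lr = lambda t, p=schedule: learning_rate(t, p)  # noqa: E731
    else:
        lr = float(schedule)
    if kind is OptimizerKind.SGD:
        return SGD(lr)
    if kind is OptimizerKind.ADAGRAD:
        return AdaGrad(lr)
    raise ValueError(f"unknown optimizer kind: {kind!r}")
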