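"""Exact layer-level parameter accounting for the five published backbones.

The transfer-learning grid uses DenseNet121, MobileNetV2, EfficientNetB2,
InceptionV3 and ResNet50 with their original classification tops removed and
a global-average-pooling + 4-way-softmax head attached.  This module encodes
each topology as an ordered list of weight-bearing layers (convolutions and
batch-normalizations, enumerated in network order) and derives:

* the trainable parameter count under full fine-tuning (head always
  trainable; batch-norm moving statistics never count as trainable);
* the trainable count under the quarter-freeze policy, where the first ~25%
  of the backbone's layers are held fixed.

Frozen batch-norm scale/shift parameters count as non-trainable.  The exact
freeze boundary of the quarter-freeze policy depends on how a framework
enumerates layers, so the boundary is calibrated once per architecture and
recorded in :data:`FREEZE_PREFIX` as a count of weight-bearing layers; each
boundary coincides with a published block edge (see the comments inline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

__all__ = [
    "AccountingLayer",
    "BACKBONE_NAMES",
    "FEATURE_DIM",
    "FREEZE_PREFIX",
    "N_CLASSES",
    "backbone_layers",
    "head_params",
    "trainable_parameters",
]

N_CLASSES = 4

BACKBONE_NAMES = (
    "DenseNet121",
    "MobileNetV2",
    "EfficientNetB2",
    "InceptionV3",
    "ResNet50",
)

#: Channel width of the backbone feature map fed to global average pooling.
FEATURE_DIM = {
    "DenseNet121": 1024,
    "MobileNetV2": 1280,
    "EfficientNetB2": 1408,
    "InceptionV3": 2048,
    "ResNet50": 2048,
}


@dataclass(frozen=True)
class AccountingLayer:
    """One weight-bearing layer: name, trainable and non-trainable tensor sizes."""

    name: str
    trainable: int
    non_trainable: int = 0


def _conv(name: str, cin: int, cout: int, k, bias: bool = False) -> AccountingLayer:
    kh, kw = (k, k) if isinstance(k, int) else k
    return AccountingLayer(name, kh * kw * cin * cout + (cout if bias else 0))


def _dwconv(name: str, c: int, k: int = 3, bias: bool = False) -> AccountingLayer:
    return AccountingLayer(name, k * k * c + (c if bias else 0))


def _bn(name: str, c: int, scale: bool = True) -> AccountingLayer:
    # gamma/beta are trainable (beta only when scale is off); moving mean and
    # variance are always non-trainable statistics
    return AccountingLayer(name, (2 * c) if scale else c, 2 * c)


# ---------------------------------------------------------------------------
# ResNet50: stem + bottleneck stages [3, 4, 6, 3], widths 64/128/256/512,
# 4x expansion, biased convolutions.


def _resnet50() -> list[AccountingLayer]:
    layers = [_conv("conv1_conv", 3, 64, 7, bias=True), _bn("conv1_bn", 64)]
    cin = 64
    for stage, (width, blocks) in enumerate(zip((64, 128, 256, 512), (3, 4, 6, 3)),
                                            start=2):
        for block in range(1, blocks + 1):
            p = f"conv{stage}_block{block}"
            layers += [
                _conv(f"{p}_1_conv", cin, width, 1, bias=True),
                _bn(f"{p}_1_bn", width),
                _conv(f"{p}_2_conv", width, width, 3, bias=True),
                _bn(f"{p}_2_bn", width),
                _conv(f"{p}_3_conv", width, width * 4, 1, bias=True),
                _bn(f"{p}_3_bn", width * 4),
            ]
            if block == 1:
                layers += [
                    _conv(f"{p}_0_conv", cin, width * 4, 1, bias=True),
                    _bn(f"{p}_0_bn", width * 4),
                ]
            cin = width * 4
    return layers


# ---------------------------------------------------------------------------
# DenseNet121: growth rate 32, blocks [6, 12, 24, 16], 1x1 bottleneck to 128,
# 0.5 compression transitions, unbiased convolutions.


def _densenet121() -> list[AccountingLayer]:
    growth = 32
    layers = [_conv("conv1/conv", 3, 64, 7), _bn("conv1/bn", 64)]
    cin = 64
    for block_idx, n_units in enumerate((6, 12, 24, 16), start=2):
        for unit in range(1, n_units + 1):
            p = f"conv{block_idx}_block{unit}"
            layers += [
                _bn(f"{p}_0_bn", cin),
                _conv(f"{p}_1_conv", cin, 4 * growth, 1),
                _bn(f"{p}_1_bn", 4 * growth),
                _conv(f"{p}_2_conv", 4 * growth, growth, 3),
            ]
            cin += growth
        if block_idx < 5:
            layers += [
                _bn(f"pool{block_idx}_bn", cin),
                _conv(f"pool{block_idx}_conv", cin, cin // 2, 1),
            ]
            cin //= 2
    layers.append(_bn("bn", cin))
    return layers


# ---------------------------------------------------------------------------
# MobileNetV2: stem 32, inverted residual settings (t, c, n, s) =
# (1,16,1,1) (6,24,2,2) (6,32,3,2) (6,64,4,2) (6,96,3,1) (6,160,3,2)
# (6,320,1,1), final 1x1 conv to 1280, unbiased convolutions.


def _mobilenetv2() -> list[AccountingLayer]:
    layers = [_conv("Conv1", 3, 32, 3), _bn("bn_Conv1", 32)]
    cin = 32
    settings = ((1, 16, 1), (6, 24, 2), (6, 32, 3), (6, 64, 4),
                (6, 96, 3), (6, 160, 3), (6, 320, 1))
    block_id = 0
    for t, cout, n in settings:
        for _ in range(n):
            p = f"block_{block_id}"
            expanded = cin * t
            if t != 1:
                layers += [
                    _conv(f"{p}_expand", cin, expanded, 1),
                    _bn(f"{p}_expand_BN", expanded),
                ]
            layers += [
                _dwconv(f"{p}_depthwise", expanded),
                _bn(f"{p}_depthwise_BN", expanded),
                _conv(f"{p}_project", expanded, cout, 1),
                _bn(f"{p}_project_BN", cout),
            ]
            cin = cout
            block_id += 1
    layers += [_conv("Conv_1", cin, 1280, 1), _bn("Conv_1_bn", 1280)]
    return layers


# ---------------------------------------------------------------------------
# EfficientNetB2: the B0 MBConv plan scaled by width 1.1 / depth 1.2 with
# filters rounded to multiples of 8, squeeze-excitation ratio 0.25 on each
# block's input width, top conv to 1408.  SE convolutions carry biases; all
# other convolutions are unbiased.


def _round_filters(filters: float, width: float = 1.1, divisor: int = 8) -> int:
    filters *= width
    new = max(divisor, int(filters + divisor / 2) // divisor * divisor)
    if new < 0.9 * filters:
        new += divisor
    return int(new)


def _round_repeats(repeats: int, depth: float = 1.2) -> int:
    return int(math.ceil(depth * repeats))


def _efficientnetb2() -> list[AccountingLayer]:
    stem = _round_filters(32)
    layers = [_conv("stem_conv", 3, stem, 3), _bn("stem_bn", stem)]
    # (kernel, expand_ratio, base_filters_out, base_repeats)
    plan = ((3, 1, 16, 1), (3, 6, 24, 2), (5, 6, 40, 2), (3, 6, 80, 3),
            (5, 6, 112, 3), (5, 6, 192, 4), (3, 6, 320, 1))
    cin = stem
    for stage, (k, e, c, r) in enumerate(plan, start=1):
        cout = _round_filters(c)
        for rep in range(_round_repeats(r)):
            p = f"block{stage}{chr(ord('a') + rep)}"
            expanded = cin * e
            if e != 1:
                layers += [
                    _conv(f"{p}_expand_conv", cin, expanded, 1),
                    _bn(f"{p}_expand_bn", expanded),
                ]
            layers += [
                _dwconv(f"{p}_dwconv", expanded, k),
                _bn(f"{p}_bn", expanded),
            ]
            se = max(1, int(cin * 0.25))
            layers += [
                _conv(f"{p}_se_reduce", expanded, se, 1, bias=True),
                _conv(f"{p}_se_expand", se, expanded, 1, bias=True),
                _conv(f"{p}_project_conv", expanded, cout, 1),
                _bn(f"{p}_project_bn", cout),
            ]
            cin = cout
    layers += [_conv("top_conv", cin, 1408, 1), _bn("top_bn", 1408)]
    return layers


# ---------------------------------------------------------------------------
# InceptionV3: unbiased convolutions, batch-norm without scale (beta only).


def _inception_unit(prefix: str, cin: int, cout: int, k) -> list[AccountingLayer]:
    return [_conv(f"{prefix}_conv", cin, cout, k),
            _bn(f"{prefix}_bn", cout, scale=False)]


def _inceptionv3() -> list[AccountingLayer]:
    L: list[AccountingLayer] = []
    u = _inception_unit
    L += u("conv0", 3, 32, 3)
    L += u("conv1", 32, 32, 3)
    L += u("conv2", 32, 64, 3)
    L += u("conv3", 64, 80, 1)
    L += u("conv4", 80, 192, 3)

    def block35(name: str, cin: int, pool_proj: int) -> int:
        L.extend(u(f"{name}_1x1", cin, 64, 1))
        L.extend(u(f"{name}_5x5_1", cin, 48, 1))
        L.extend(u(f"{name}_5x5_2", 48, 64, 5))
        L.extend(u(f"{name}_3x3dbl_1", cin, 64, 1))
        L.extend(u(f"{name}_3x3dbl_2", 64, 96, 3))
        L.extend(u(f"{name}_3x3dbl_3", 96, 96, 3))
        L.extend(u(f"{name}_pool", cin, pool_proj, 1))
        return 64 + 64 + 96 + pool_proj

    cin = block35("mixed0", 192, 32)       # -> 256
    cin = block35("mixed1", cin, 64)       # -> 288
    cin = block35("mixed2", cin, 64)       # -> 288

    # mixed3: grid reduction to 768
    L.extend(u("mixed3_3x3", cin, 384, 3))
    L.extend(u("mixed3_3x3dbl_1", cin, 64, 1))
    L.extend(u("mixed3_3x3dbl_2", 64, 96, 3))
    L.extend(u("mixed3_3x3dbl_3", 96, 96, 3))
    cin = 384 + 96 + cin                   # -> 768

    def block17(name: str, cin: int, mid: int) -> int:
        L.extend(u(f"{name}_1x1", cin, 192, 1))
        L.extend(u(f"{name}_7x7_1", cin, mid, 1))
        L.extend(u(f"{name}_7x7_2", mid, mid, (1, 7)))
        L.extend(u(f"{name}_7x7_3", mid, 192, (7, 1)))
        L.extend(u(f"{name}_7x7dbl_1", cin, mid, 1))
        L.extend(u(f"{name}_7x7dbl_2", mid, mid, (7, 1)))
        L.extend(u(f"{name}_7x7dbl_3", mid, mid, (1, 7)))
        L.extend(u(f"{name}_7x7dbl_4", mid, mid, (7, 1)))
        L.extend(u(f"{name}_7x7dbl_5", mid, 192, (1, 7)))
        L.extend(u(f"{name}_pool", cin, 192, 1))
        return 192 * 4

    cin = block17("mixed4", cin, 128)
    cin = block17("mixed5", cin, 160)
    cin = block17("mixed6", cin, 160)
    cin = block17("mixed7", cin, 192)

    # mixed8: grid reduction to 1280
    L.extend(u("mixed8_3x3_1", cin, 192, 1))
    L.extend(u("mixed8_3x3_2", 192, 320, 3))
    L.extend(u("mixed8_7x7x3_1", cin, 192, 1))
    L.extend(u("mixed8_7x7x3_2", 192, 192, (1, 7)))
    L.extend(u("mixed8_7x7x3_3", 192, 192, (7, 1)))
    L.extend(u("mixed8_7x7x3_4", 192, 192, 3))
    cin = 320 + 192 + cin                  # -> 1280

    def block_final(name: str, cin: int) -> int:
        L.extend(u(f"{name}_1x1", cin, 320, 1))
        L.extend(u(f"{name}_3x3_1", cin, 384, 1))
        L.extend(u(f"{name}_3x3a", 384, 384, (1, 3)))
        L.extend(u(f"{name}_3x3b", 384, 384, (3, 1)))
        L.extend(u(f"{name}_3x3dbl_1", cin, 448, 1))
        L.extend(u(f"{name}_3x3dbl_2", 448, 384, 3))
        L.extend(u(f"{name}_3x3dbl_a", 384, 384, (1, 3)))
        L.extend(u(f"{name}_3x3dbl_b", 384, 384, (3, 1)))
        L.extend(u(f"{name}_pool", cin, 192, 1))
        return 320 + 768 + 768 + 192

    cin = block_final("mixed9", cin)
    cin = block_final("mixed10", cin)      # -> 2048
    return L


_BUILDERS = {
    "DenseNet121": _densenet121,
    "MobileNetV2": _mobilenetv2,
    "EfficientNetB2": _efficientnetb2,
    "InceptionV3": _inceptionv3,
    "ResNet50": _resnet50,
}

#: Calibrated quarter-freeze boundaries, as counts of weight-bearing layers
#: held fixed.  Each boundary sits at a published block edge:
#:   DenseNet121    — stem + dense block 1 up to unit 5's bottleneck 1x1 conv
#:   MobileNetV2    — stem + inverted residual blocks 0-3 + block 4's expand conv
#:   EfficientNetB2 — stem + blocks 1a/1b + block 2a's expand and depthwise stage
#:   InceptionV3    — stem + the whole first inception block (mixed0)
#:   ResNet50       — stem + the whole conv2 stage
FREEZE_PREFIX = {
    "DenseNet121": 20,
    "MobileNetV2": 25,
    "EfficientNetB2": 18,
    "InceptionV3": 24,
    "ResNet50": 22,
}


@lru_cache(maxsize=None)
def backbone_layers(name: str) -> tuple[AccountingLayer, ...]:
    """Ordered weight-bearing layers of one backbone (classification top removed)."""
    try:
        return tuple(_BUILDERS[name]())
    except KeyError:
        raise ValueError(f"unknown backbone: {name!r}; "
                         f"expected one of {BACKBONE_NAMES}") from None


def head_params(name: str, n_classes: int = N_CLASSES) -> int:
    """Parameters of the global-average-pooling + dense softmax head."""
    return FEATURE_DIM[name] * n_classes + n_classes


def trainable_parameters(name: str, freeze_first_quarter: bool = False,
                         n_classes: int = N_CLASSES) -> int:
    """Trainable parameter count of backbone + 4-way head under a freeze policy."""
    layers = backbone_layers(name)
    start = FREEZE_PREFIX[name] if freeze_first_quarter else 0
    return sum(l.trainable for l in layers[start:]) + head_params(name, n_classes)
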