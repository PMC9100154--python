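"""Architecture registry: the five canonical backbones and the smoke family.

Canonical specs carry the published input size, backbone feature width and
per-architecture normalization convention.  The smoke family is a set of
five small, mutually distinct CNNs that train in seconds on a CPU; it
exists so that the full grid -> ensemble -> statistics pipeline can be run
end to end without GPUs or downloaded weights, with the same contracts as
the canonical architectures.
"""

from __future__ import annotations

from dataclasses import dataclass

from celltax.backbone_accounting import BACKBONE_NAMES, FEATURE_DIM
from celltax.patch_pipeline import NormalizationMode

__all__ = ["ArchSpec", "CANONICAL_ARCHS", "SMOKE_ARCHS", "ALL_ARCHS", "get_arch"]


@dataclass(frozen=True)
class ArchSpec:
    """One classifier architecture and its input contract."""

    name: str
    input_size: int
    feature_dim: int
    normalization: NormalizationMode
    family: str = "canonical"          # "canonical" or "smoke"
    conv_widths: tuple[int, ...] = ()  # smoke family only

    @property
    def is_trainable_in_package(self) -> bool:
        return self.family == "smoke"


_CANONICAL_INPUT = {
    "DenseNet121": 224,
    "MobileNetV2": 224,
    "EfficientNetB2": 260,
    "InceptionV3": 299,
    "ResNet50": 224,
}

# Published preprocessing convention per backbone family.
_CANONICAL_NORM = {
    "DenseNet121": NormalizationMode.UNIT_RANGE_IMAGENET,
    "ResNet50": NormalizationMode.BGR_MEAN_CENTER,
    "MobileNetV2": NormalizationMode.SYMMETRIC_UNIT,
    "InceptionV3": NormalizationMode.SYMMETRIC_UNIT,
    "EfficientNetB2": NormalizationMode.UNIT_RANGE_SAMPLEWISE,
}

CANONICAL_ARCHS: dict[str, ArchSpec] = {
    name: ArchSpec(name=name, input_size=_CANONICAL_INPUT[name],
                   feature_dim=FEATURE_DIM[name],
                   normalization=_CANONICAL_NORM[name])
    for name in BACKBONE_NAMES
}

# Five small architectures, pairwise distinct in width, ordered smallest
# first; normalization modes are spread over the family so every mode is
# exercised end to end.
_SMOKE_PLAN = (
    ("micronet-a", (8, 16), NormalizationMode.SYMMETRIC_UNIT),
    ("micronet-b", (10, 20), NormalizationMode.UNIT_RANGE_SAMPLEWISE),
    ("micronet-c", (12, 24), NormalizationMode.UNIT_RANGE_IMAGENET),
    ("micronet-d", (14, 28), NormalizationMode.BGR_MEAN_CENTER),
    ("micronet-e", (16, 32), NormalizationMode.SYMMETRIC_UNIT),
)

SMOKE_ARCHS: dict[str, ArchSpec] = {
    name: ArchSpec(name=name, input_size=32, feature_dim=widths[-1],
                   normalization=norm, family="smoke", conv_widths=widths)
    for name, widths, norm in _SMOKE_PLAN
}

ALL_ARCHS: dict[str, ArchSpec] = {**CANONICAL_ARCHS, **SMOKE_ARCHS}


def get_arch(name: str) -> ArchSpec:
    try:
        return ALL_ARCHS[name]
    except KeyError:
        raise ValueError(
            f"unknown architecture {name!r}; known: {sorted(ALL_ARCHS)}"
        ) from None
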