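"""Patch-level input preparation: resize, per-architecture normalization,
and on-the-fly geometric augmentation.

Each backbone family publishes its own input convention, so patches are
normalized differently per architecture:

* ``UNIT_RANGE_IMAGENET`` — scale to [0, 1] then standardize per channel
  with the ImageNet statistics (mu 0.485/0.456/0.406, sigma 0.229/0.224/0.225, RGB);
* ``BGR_MEAN_CENTER`` — swap RGB to BGR, subtract the ImageNet channel means
  on the 0-255 scale (103.939/116.779/123.68, BGR), no scaling;
* ``SYMMETRIC_UNIT`` — v / 127.5 - 1, mapping [0, 255] onto [-1, 1];
* ``UNIT_RANGE_SAMPLEWISE`` — v / 255 per sample.

Augmentation follows the spatial scheme used for microscopy patches: random
rotation uniform in [0, 90] degrees, integer translation up to +-2 px per
axis, and a vertical flip with probability 0.5, with exposed borders filled
by edge replication.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage.transform import resize as _sk_resize, rotate as _sk_rotate

from celltax.segmentation import CellPatch

__all__ = [
    "NormalizationMode",
    "AugmentationParams",
    "IMAGENET_MEAN_RGB",
    "IMAGENET_STD_RGB",
    "IMAGENET_MEAN_BGR_255",
    "normalize",
    "normalize_array",
    "augment",
    "resize_patch",
]

IMAGENET_MEAN_RGB = np.array([0.485, 0.456, 0.406])
IMAGENET_STD_RGB = np.array([0.229, 0.224, 0.225])
IMAGENET_MEAN_BGR_255 = np.array([103.939, 116.779, 123.68])


class NormalizationMode(Enum):
    UNIT_RANGE_IMAGENET = "unit_range_imagenet"
    BGR_MEAN_CENTER = "bgr_mean_center"
    SYMMETRIC_UNIT = "symmetric_unit"
    UNIT_RANGE_SAMPLEWISE = "unit_range_samplewise"


@dataclass(frozen=True)
class AugmentationParams:
    """Spatial augmentation scheme (rotation, +-2 px shifts, vertical flip)."""

    rotation_range: float = 90.0
    translation: int = 2
    vertical_flip_prob: float = 0.5
    enabled: bool = True


def normalize_array(pixels: np.ndarray, mode: NormalizationMode) -> np.ndarray:
    """Apply one normalization mode to an (..., 3) uint8/float RGB array."""
    x = np.asarray(pixels, dtype=np.float64)
    if x.ndim < 3 or x.shape[-1] != 3:
        raise ValueError("expected an (..., H, W, 3) array")
    if mode is NormalizationMode.SYMMETRIC_UNIT:
        return x / 127.5 - 1.0
    if mode is NormalizationMode.UNIT_RANGE_SAMPLEWISE:
        return x / 255.0
    if mode is NormalizationMode.UNIT_RANGE_IMAGENET:
        return (x / 255.0 - IMAGENET_MEAN_RGB) / IMAGENET_STD_RGB
    if mode is NormalizationMode.BGR_MEAN_CENTER:
        return x[..., ::-1] - IMAGENET_MEAN_BGR_255
    raise ValueError(f"unknown normalization mode: {mode!r}")


def normalize(patch: CellPatch, arch) -> np.ndarray:
    """Normalize a patch for one architecture (``arch.normalization`` mode)."""
    mode = arch if isinstance(arch, NormalizationMode) else arch.normalization
    return normalize_array(patch.pixels, mode)


def augment(patch: CellPatch, params: AugmentationParams, seed: int) -> CellPatch:
    """Randomly rotate, translate and flip one patch (deterministic per seed).

    The output has the same shape and 8-bit range as the input; borders
    exposed by rotation or translation are filled by edge replication.
    """
    if not params.enabled:
        return patch
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0.0, params.rotation_range)
    dx = int(rng.integers(-params.translation, params.translation + 1))
    dy = int(rng.integers(-params.translation, params.translation + 1))
    flip = rng.random() < params.vertical_flip_prob

    out = patch.pixels.astype(np.float64)
    if angle != 0.0:
        out = _sk_rotate(out, angle, resize=False, mode="edge",
                         preserve_range=True, order=1)
    if dx or dy:
        shifted = np.empty_like(out)
        src = np.roll(out, shift=(dy, dx), axis=(0, 1))
        shifted[:] = src
        # edge replication for the wrapped-in margins
        if dy > 0:
            shifted[:dy] = shifted[dy:dy + 1]
        elif dy < 0:
            shifted[dy:] = shifted[dy - 1:dy]
        if dx > 0:
            shifted[:, :dx] = shifted[:, dx:dx + 1]
        elif dx < 0:
            shifted[:, dx:] = shifted[:, dx - 1:dx]
        out = shifted
    if flip:
        out = out[::-1]
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return CellPatch(pixels=out, box=patch.box, label=patch.label)


def resize_patch(patch: CellPatch, target: int) -> CellPatch:
    """Bilinear resize to ``target x target`` (aspect ratio not preserved)."""
    if target <= 0:
        raise ValueError("target size must be positive")
    if patch.pixels.size == 0:
        raise ValueError("cannot resize an empty patch")
    if patch.pixels.shape[:2] == (target, target):
        return CellPatch(pixels=patch.pixels.copy(), box=patch.box,
                         label=patch.label)
    out = _sk_resize(patch.pixels.astype(np.float64), (target, target),
                     order=1, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return CellPatch(pixels=out, box=patch.box, label=patch.label)
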