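"""Classical brightfield segmentation: threshold, clean, box, filter, crop.

Cells appear dark on a bright field, so the chain is: grayscale conversion,
local-mean adaptive thresholding (foreground = darker than the local mean by
more than an offset), a 2x2 dilation to consolidate fragmented contours,
tight bounding boxes over 8-connected components, a size filter that drops
boxes with ``w + h < 100`` (uninformative cells and floating debris), and
finally patch crops taken from the original colour image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationParams",
    "CellBox",
    "CellPatch",
    "to_grayscale",
    "binarize_and_clean",
    "find_cell_boxes",
    "filter_boxes",
    "extract_patches",
    "segment_image",
    "box_iou",
    "match_boxes",
]

#: Luma weights for RGB -> grayscale conversion (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the segmentation chain.

    ``threshold_window`` is the side of the square local-mean window (odd,
    pixels), ``threshold_offset`` the intensity margin below the local mean
    required to call a pixel foreground, and ``min_box_sum`` the ``w + h``
    size-filter threshold (fixed at 100 unless explicitly overridden).
    """

    threshold_window: int = 51
    threshold_offset: float = 5.0
    dilation_iterations: int = 1
    min_box_sum: int = 100

    def __post_init__(self) -> None:
        if self.threshold_window < 3 or self.threshold_window % 2 == 0:
            raise ValueError("threshold_window must be odd and >= 3")
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")


@dataclass(frozen=True)
class CellBox:
    """Axis-aligned box, 0-based, half-open: [x, x+w) x [y, y+h)."""

    x: int
    y: int
    w: int
    h: int
    source_image_id: str = ""

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box must have positive width and height")

    @property
    def box_sum(self) -> int:
        return self.w + self.h


@dataclass
class CellPatch:
    """Colour crop of one detected cell, pre-resize, with provenance."""

    pixels: np.ndarray
    box: CellBox
    label: int | None = None


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 3-channel 8-bit image to grayscale with standard luma weights."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    gray = image.astype(np.float64) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def binarize_and_clean(gray: np.ndarray, params: SegmentationParams | None = None
                       ) -> np.ndarray:
    """Adaptive local-mean threshold (dark = foreground) followed by 2x2 dilation."""
    params = params or SegmentationParams()
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    if params.threshold_window > min(gray.shape):
        raise ValueError("threshold_window larger than the image")
    local_mean = ndimage.uniform_filter(gray.astype(np.float64),
                                        size=params.threshold_window,
                                        mode="reflect")
    binary = gray.astype(np.float64) < (local_mean - params.threshold_offset)
    if params.dilation_iterations > 0:
        binary = ndimage.binary_dilation(binary, structure=np.ones((2, 2), bool),
                                         iterations=params.dilation_iterations)
    return binary


def find_cell_boxes(binary: np.ndarray, source_image_id: str = "") -> list[CellBox]:
    """Tight bounding box of every 8-connected foreground component."""
    labelled, n = ndimage.label(binary, structure=np.ones((3, 3), bool))
    boxes: list[CellBox] = []
    for sl in ndimage.find_objects(labelled):
        if sl is None:
            continue
        ys, xs = sl
        boxes.append(CellBox(x=int(xs.start), y=int(ys.start),
                             w=int(xs.stop - xs.start), h=int(ys.stop - ys.start),
                             source_image_id=source_image_id))
    return boxes


def filter_boxes(boxes: list[CellBox], min_box_sum: int = 100) -> list[CellBox]:
    """Keep boxes with ``w + h >= min_box_sum`` (order preserved, idempotent)."""
    if min_box_sum < 0:
        raise ValueError("min_box_sum must be >= 0")
    return [b for b in boxes if b.w + b.h >= min_box_sum]


def extract_patches(image: np.ndarray, boxes: list[CellBox],
                    label: int | None = None) -> list[CellPatch]:
    """Crop each box out of the ORIGINAL colour image (not the binary mask)."""
    h, w = image.shape[:2]
    patches = []
    for box in boxes:
        if box.x < 0 or box.y < 0 or box.x + box.w > w or box.y + box.h > h:
            raise ValueError(f"box {box} out of image bounds {w}x{h}")
        crop = image[box.y:box.y + box.h, box.x:box.x + box.w].copy()
        patches.append(CellPatch(pixels=crop, box=box, label=label))
    return patches


def segment_image(image: np.ndarray, params: SegmentationParams | None = None,
                  source_image_id: str = "", label: int | None = None
                  ) -> list[CellPatch]:
    """Full chain: grayscale -> threshold -> dilate -> boxes -> filter -> crops."""
    params = params or SegmentationParams()
    gray = to_grayscale(image)
    binary = binarize_and_clean(gray, params)
    boxes = find_cell_boxes(binary, source_image_id)
    kept = filter_boxes(boxes, params.min_box_sum)
    return extract_patches(image, kept, label=label)


# ---------------------------------------------------------------------------
# evaluation helpers


def box_iou(a, b) -> float:
    """Intersection-over-union of two boxes with .x/.y/.w/.h fields."""
    x0 = max(a.x, b.x)
    y0 = max(a.y, b.y)
    x1 = min(a.x + a.w, b.x + b.w)
    y1 = min(a.y + a.h, b.y + b.h)
    inter = max(x1 - x0, 0) * max(y1 - y0, 0)
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union > 0 else 0.0


def match_boxes(predicted, truth, iou_threshold: float = 0.5
                ) -> tuple[int, int, int]:
    """Greedy one-to-one matching; returns (true positives, false pos, false neg)."""
    unmatched = list(range(len(truth)))
    tp = 0
    for p in predicted:
        best, best_iou = None, iou_threshold
        for idx in unmatched:
            iou = box_iou(p, truth[idx])
            if iou >= best_iou:
                best, best_iou = idx, iou
        if best is not None:
            unmatched.remove(best)
            tp += 1
    fp = len(predicted) - tp
    fn = len(truth) - tp
    return tp, fp, fn
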