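"""Per-seed mask construction.

Two binary masks are built for every seed image stack:

* ``m1`` — the segmentation mask delimiting the seed, used for size and
  shape measurement;
* ``m2`` — ``m1`` further restricted to pixels whose surface height
  exceeds a threshold (default 20 height units), used for colour and
  height measurement so that near-zero-height boundary pixels, whose
  intensities are corrupted by shadowing, are excluded.

Connectivity conventions: 4-connectivity for connected components,
8-connectivity for the boundary test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import ImageStack

__all__ = ["MaskPair", "SegmentationError", "segment_seed", "height_mask", "build_masks"]

DEFAULT_HEIGHT_THRESHOLD = 20.0

#: Height floor (units) separating seed from the zero background.
SEGMENTATION_FLOOR = 1.0

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class SegmentationError(ValueError):
    """Raised when no usable seed region can be found."""


@dataclass(frozen=True)
class MaskPair:
    """The (m1, m2) mask pair for one seed."""

    m1: np.ndarray
    m2: np.ndarray
    height_threshold: float = DEFAULT_HEIGHT_THRESHOLD

    def __post_init__(self) -> None:
        if self.m1.shape != self.m2.shape:
            raise ValueError("m1 and m2 must have the same shape")
        if not self.m1.any() or not self.m2.any():
            raise ValueError("masks must be non-empty")
        if np.any(self.m2 & ~self.m1):
            raise ValueError("m2 must be a subset of m1")


def segment_seed(stack: ImageStack, floor: float = SEGMENTATION_FLOOR) -> np.ndarray:
    """Segment the seed from its zero background: m1.

    Thresholds the height image at a small floor, applies a 3x3
    morphological closing, fills interior holes, and keeps the largest
    4-connected component.
    """
    if not np.any(stack.height > 0):
        raise SegmentationError("no seed found: height image is all zero")
    mask = stack.height > floor
    if not mask.any():
        raise SegmentationError("no seed found: no height above segmentation floor")
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), dtype=bool))
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_4)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if not mask.any():
        raise SegmentationError("no seed found after morphology")
    return mask


def height_mask(
    stack: ImageStack, m1: np.ndarray, threshold: float = DEFAULT_HEIGHT_THRESHOLD
) -> np.ndarray:
    """Restrict m1 to pixels with height strictly above ``threshold``: m2."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not m1.any():
        raise SegmentationError("m1 is empty")
    m2 = m1 & (stack.height > threshold)
    if not m2.any():
        raise SegmentationError(f"seed below height threshold {threshold}")
    return m2


def build_masks(stack: ImageStack, threshold: float = DEFAULT_HEIGHT_THRESHOLD) -> MaskPair:
    """Convenience: segment then height-threshold."""
    m1 = segment_seed(stack)
    m2 = height_mask(stack, m1, threshold)
    return MaskPair(m1=m1, m2=m2, height_threshold=threshold)
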