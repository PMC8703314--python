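"""Morphological cleanup of raw thresholded masks.

Raw saliency thresholding leaves two artifact classes: isolated speckle
(smaller than the tumor scale) and spurious responses hugging the image
border/corners.  Cleanup is a 3x3 morphological opening, then removal of
8-connected components confined to a thin border band, then an optional
minimum-size filter.  Every step is anti-extensive: pixels are only ever
removed, never added.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError

__all__ = [
    "PostprocessConfig",
    "remove_border_components",
    "morphological_opening",
    "postprocess_mask",
]

#: 8-connectivity structuring element for component labeling.
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class PostprocessConfig:
    corner_margin: int = 10       # px; border band whose confined components die
    opening_kernel: int = 3       # odd side of the square opening element
    min_component_px: int = 0     # 0 disables the size filter

    def __post_init__(self) -> None:
        if self.opening_kernel < 1 or self.opening_kernel % 2 == 0:
            raise ValidationError("opening_kernel must be odd and >= 1")
        if self.corner_margin < 0 or self.min_component_px < 0:
            raise ValidationError("corner_margin and min_component_px must be >= 0")

    def to_dict(self) -> dict:
        return {
            "corner_margin": self.corner_margin,
            "opening_kernel": self.opening_kernel,
            "min_component_px": self.min_component_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PostprocessConfig":
        return cls(**d)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError("mask must be binary (0/1)")
    return arr.astype(bool)


def remove_border_components(mask: np.ndarray, margin: int = 10) -> np.ndarray:
    """Delete 8-connected components that live entirely within ``margin``
    pixels of the image border; any component with one interior pixel
    survives whole."""
    m = _check_mask(mask)
    if margin == 0 or not m.any():
        return m.astype(np.uint8)
    interior = np.zeros_like(m)
    r, c = m.shape
    if r > 2 * margin and c > 2 * margin:
        interior[margin : r - margin, margin : c - margin] = True
    labels, n = ndimage.label(m, structure=_EIGHT)
    if n == 0:
        return m.astype(np.uint8)
    keep = np.zeros(n + 1, dtype=bool)
    inner_labels = np.unique(labels[interior & m]) if interior.any() else []
    keep[list(inner_labels)] = True
    keep[0] = False
    return keep[labels].astype(np.uint8)


def morphological_opening(mask: np.ndarray, kernel_side: int = 3) -> np.ndarray:
    """Erosion then dilation with a square all-ones element.

    Removes structures that cannot contain the element (an isolated pixel
    dies under a 3x3 kernel); shapes at least as large as the element are
    preserved exactly.  Idempotent and anti-extensive.
    """
    m = _check_mask(mask)
    if kernel_side < 1 or kernel_side % 2 == 0:
        raise ValidationError("kernel side must be odd and >= 1")
    if kernel_side == 1:
        return m.astype(np.uint8)
    element = np.ones((kernel_side, kernel_side), dtype=bool)
    return ndimage.binary_opening(m, structure=element).astype(np.uint8)


def postprocess_mask(
    mask: np.ndarray, cfg: PostprocessConfig | None = None
) -> np.ndarray:
    """Opening, then border-component removal, then the optional size filter.

    Opening runs first so that a thin bridge between a border artifact and
    real tumor is cut before components are labeled.  The pixel count never
    increases.
    """
    cfg = cfg or PostprocessConfig()
    m = morphological_opening(mask, cfg.opening_kernel)
    m = remove_border_components(m, cfg.corner_margin)
    if cfg.min_component_px > 0 and m.any():
        labels, n = ndimage.label(m.astype(bool), structure=_EIGHT)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes >= cfg.min_component_px
        m = keep[labels].astype(np.uint8)
    return m
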