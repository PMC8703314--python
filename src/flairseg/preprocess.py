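"""Per-slice z-score normalization and the training-set augmentation suite.

Augmentation enlarges the labeled slice set with simple, label-preserving
transforms: horizontal/vertical flips, exact quarter-turn rotations, integer
pixel shifts, additive Gaussian noise and Gaussian blur.  Geometric
transforms are applied identically to a ground-truth mask when one rides
along, so mask/slice pairing survives augmentation.

Normalization (zero mean, unit variance per slice) is applied after
augmentation, immediately before the network input, because noise and blur
change a slice's moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateInputError, ValidationError
from .io_slices import Slice2D

__all__ = [
    "AugmentConfig",
    "zscore_normalize",
    "flip_h",
    "flip_v",
    "rotate90",
    "shift",
    "add_noise",
    "gaussian_blur",
    "build_augmented_dataset",
]


@dataclass
class AugmentConfig:
    """Which transforms to apply and how strongly.

    ``sample_flips`` mirrors the 50%-probability flip rows: in sampling mode
    each flip is applied to a random half of the inputs; in exhaustive mode
    every enabled transform is applied to every input.
    """

    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    rotation_deg: int = 90          # quarter-turns in both directions
    shift_px: int = 20
    noise_sigma: float = 0.05       # fraction of the slice intensity range
    blur_sigma: float = 1.0         # pixels
    seed: int = 0
    sample_flips: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_flip_h <= 1.0 and 0.0 <= self.p_flip_v <= 1.0):
            raise ValidationError("flip probabilities must lie in [0, 1]")
        if self.shift_px < 0 or self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValidationError("shift_px, noise_sigma, blur_sigma must be >= 0")
        if abs(self.rotation_deg) != 90 and self.rotation_deg != 0:
            raise ValidationError("only 0 or +/-90 degree rotations are supported")

    def to_dict(self) -> dict:
        return {
            "p_flip_h": self.p_flip_h,
            "p_flip_v": self.p_flip_v,
            "rotation_deg": self.rotation_deg,
            "shift_px": self.shift_px,
            "noise_sigma": self.noise_sigma,
            "blur_sigma": self.blur_sigma,
            "seed": self.seed,
            "sample_flips": self.sample_flips,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentConfig":
        return cls(**d)


def zscore_normalize(s: Slice2D) -> Slice2D:
    """Center the slice on zero and scale to unit (population) std.

    Raises :class:`DegenerateInputError` on a constant image, where the
    standard deviation is zero and the transform is undefined.
    """
    mu = s.pixels.mean()
    sigma = s.pixels.std()
    if sigma == 0.0:
        raise DegenerateInputError("cannot z-score a constant image (sigma = 0)")
    return s.with_pixels((s.pixels - mu) / sigma)


def flip_h(s: Slice2D) -> Slice2D:
    """Mirror left-right (columns reversed)."""
    return s.with_pixels(s.pixels[:, ::-1].copy())


def flip_v(s: Slice2D) -> Slice2D:
    """Mirror top-bottom (rows reversed)."""
    return s.with_pixels(s.pixels[::-1, :].copy())


def rotate90(s: Slice2D, direction: int = +90) -> Slice2D:
    """Exact quarter-turn; +90 is counter-clockwise, -90 clockwise."""
    if direction == +90:
        return s.with_pixels(np.rot90(s.pixels, 1).copy())
    if direction == -90:
        return s.with_pixels(np.rot90(s.pixels, -1).copy())
    raise ValidationError(f"direction must be +90 or -90, got {direction}")


def shift(s: Slice2D, dx: int, dy: int) -> Slice2D:
    """Translate by (dx columns, dy rows); vacated pixels are zero-filled.

    Zero is the background value of brain MRI, so zero-fill introduces no
    artificial structure.
    """
    r, c = s.shape
    if abs(dx) >= c or abs(dy) >= r:
        raise ValidationError(f"shift ({dx},{dy}) moves content fully out of frame")
    out = np.zeros_like(s.pixels)
    src_r = slice(max(0, -dy), min(r, r - dy))
    dst_r = slice(max(0, dy), min(r, r + dy))
    src_c = slice(max(0, -dx), min(c, c - dx))
    dst_c = slice(max(0, dx), min(c, c + dx))
    out[dst_r, dst_c] = s.pixels[src_r, src_c]
    return s.with_pixels(out)


def add_noise(s: Slice2D, sigma: float, rng: np.random.Generator) -> Slice2D:
    """Additive zero-mean Gaussian noise, std = sigma * (intensity range)."""
    if sigma < 0:
        raise ValidationError("noise sigma must be >= 0")
    if sigma == 0:
        return s.with_pixels(s.pixels.copy())
    scale = sigma * float(s.pixels.max() - s.pixels.min())
    return s.with_pixels(s.pixels + rng.normal(0.0, scale, size=s.shape))


def gaussian_blur(s: Slice2D, sigma: float) -> Slice2D:
    """Gaussian-kernel smoothing with reflective boundary handling."""
    if sigma < 0:
        raise ValidationError("blur sigma must be >= 0")
    if sigma == 0:
        return s.with_pixels(s.pixels.copy())
    return s.with_pixels(gaussian_filter(s.pixels, sigma=sigma, mode="reflect"))


def _geometric_transforms(cfg: AugmentConfig):
    """(name, slice_fn, applies_to_mask) triples for the enabled transforms."""
    ops = []
    if cfg.rotation_deg == 90:
        ops.append(("rot+90", lambda s: rotate90(s, +90), True))
        ops.append(("rot-90", lambda s: rotate90(s, -90), True))
    if cfg.shift_px > 0:
        d = cfg.shift_px
        ops.append(("shift", lambda s: shift(s, d, d), True))
    return ops


def build_augmented_dataset(
    slices: Sequence[Slice2D],
    labels: Sequence[int],
    cfg: AugmentConfig,
    masks: Sequence[np.ndarray] | None = None,
) -> dict:
    """Originals plus transformed copies, each keeping its source label.

    Returns a dict with keys ``slices``, ``labels``, ``provenance`` (which
    transform produced each item) and, when ``masks`` is given, ``masks``
    transformed by the identical geometric operation.  Fully reproducible
    from ``cfg.seed``.
    """
    if len(slices) != len(labels):
        raise ValidationError(
            f"{len(slices)} slices but {len(labels)} labels"
        )
    if masks is not None and len(masks) != len(slices):
        raise ValidationError("masks, when given, must pair 1:1 with slices")

    rng = np.random.default_rng(cfg.seed)
    out_slices: list[Slice2D] = []
    out_labels: list[int] = []
    out_masks: list[np.ndarray] | None = [] if masks is not None else None
    provenance: list[str] = []

    def emit(sl: Slice2D, lab: int, mk: np.ndarray | None, tag: str) -> None:
        out_slices.append(sl)
        out_labels.append(int(lab))
        provenance.append(tag)
        if out_masks is not None:
            out_masks.append(mk)

    geo = _geometric_transforms(cfg)
    for i, (sl, lab) in enumerate(zip(slices, labels)):
        mk = masks[i] if masks is not None else None
        emit(sl, lab, mk, "original")

        def mask_slice(m: np.ndarray) -> Slice2D:
            return Slice2D(pixels=np.asarray(m, dtype=float))

        # flips: sampled at their stated probability, or forced in exhaustive mode
        for name, fn, p in (
            ("flip_h", flip_h, cfg.p_flip_h),
            ("flip_v", flip_v, cfg.p_flip_v),
        ):
            take = (rng.random() < p) if cfg.sample_flips else (p > 0)
            if take:
                emit(
                    fn(sl),
                    lab,
                    fn(mask_slice(mk)).pixels if mk is not None else None,
                    name,
                )
        for name, fn, applies in geo:
            emit(
                fn(sl),
                lab,
                fn(mask_slice(mk)).pixels if mk is not None else None,
                name,
            )
        # intensity transforms leave the mask untouched
        if cfg.noise_sigma > 0:
            emit(add_noise(sl, cfg.noise_sigma, rng), lab, mk, "noise")
        if cfg.blur_sigma > 0:
            emit(gaussian_blur(sl, cfg.blur_sigma), lab, mk, "blur")

    result = {
        "slices": out_slices,
        "labels": np.asarray(out_labels, dtype=int),
        "provenance": provenance,
    }
    if out_masks is not None:
        result["masks"] = out_masks
    return result
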