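"""Mask-free tumor segmentation from feature-map spatial gradients.

Given the 32 post-ReLU maps of the classifier's last convolution, the
segmentation stage:

1. computes per-map forward-difference gradients
   H[i,j] = X[i,j+1] - X[i,j],  V[i,j] = X[i+1,j] - X[i,j]
   (spatial intensity gradients of the feature images — not back-propagated
   class gradients);
2. scalarizes them to a per-pixel magnitude sqrt(H^2 + V^2);
3. pools each magnitude map to its average and its global maximum, giving
   two 32-vectors of per-map importance weights;
4. re-weights each feature map by its combined weight (mean_k * max_k),
   keeping 32 maps;
5. averages the weighted maps into one image, clamps negatives, scales to
   [0, 1] grayscale;
6. upsamples to slice resolution, thresholds (either a fixed tau or a sweep
   over tau = 0.33, 0.35, ..., 0.85 scored by Dice against a reference),
   post-processes, and renders a jet-colormap overlay.

Maps whose activations form sharp, compact, high-contrast structure — the
hyperintense tumor on FLAIR — carry large gradient weights; flat or diffuse
maps are suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps
from skimage.transform import resize

from .cnn import FeatureStack, Network, classify
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    NoTumorDetected,
    ValidationError,
)
from .io_slices import Slice2D
from .metrics import dice
from .postprocess import PostprocessConfig, postprocess_mask

__all__ = [
    "GradientStack",
    "PooledWeights",
    "SaliencyMap",
    "SegMask",
    "DEFAULT_TAUS",
    "spatial_gradient",
    "gradient_magnitude",
    "pool_gradient_weights",
    "weight_feature_maps",
    "mean_saliency",
    "normalize_to_grayscale",
    "upsample_saliency",
    "apply_colormap",
    "superimpose",
    "threshold_mask",
    "threshold_sweep",
    "segment_slice",
]

#: Published threshold grid: 0.33 to 0.85 inclusive in steps of 0.02.
DEFAULT_TAUS = tuple(np.round(np.arange(0.33, 0.85 + 1e-9, 0.02), 2))

#: Deployment threshold when no reference mask is available.
DEFAULT_FIXED_TAU = 0.5

#: Default overlay blending weight.
DEFAULT_ALPHA = 0.4


@dataclass
class GradientStack:
    """Per-map forward differences and their scalar magnitudes."""

    H: np.ndarray          # (n, s, s) horizontal differences
    V: np.ndarray          # (n, s, s) vertical differences
    magnitude: np.ndarray  # (n, s, s) sqrt(H^2 + V^2)


@dataclass
class PooledWeights:
    """Average and global-max gradient magnitude, one entry per map."""

    mean_vec: np.ndarray
    max_vec: np.ndarray

    def __post_init__(self) -> None:
        self.mean_vec = np.asarray(self.mean_vec, dtype=np.float64)
        self.max_vec = np.asarray(self.max_vec, dtype=np.float64)
        if self.mean_vec.shape != self.max_vec.shape or self.mean_vec.ndim != 1:
            raise ValidationError("pooled weight vectors must be equal-length 1-D")


@dataclass
class SaliencyMap:
    """Single grayscale evidence map in [0, 1]."""

    gray: np.ndarray
    source_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.gray = np.asarray(self.gray, dtype=np.float64)
        if self.gray.ndim != 2:
            raise ValidationError("saliency map must be 2-D")
        if self.gray.min() < 0 or self.gray.max() > 1:
            raise ValidationError("saliency values must lie in [0, 1]")


@dataclass
class SegMask:
    """Binary tumor mask plus the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float
    provenance: str = "fixed"  # "fixed" or "sweep"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise ValidationError("mask values must be 0/1")
        self.mask = self.mask.astype(np.uint8)


def spatial_gradient(map2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with unit step.

    H[i, j] = X[i, j+1] - X[i, j] (last column 0);
    V[i, j] = X[i+1, j] - X[i, j] (last row 0).
    The differences are undefined on the trailing edge, where zero is the
    neutral choice for downstream mean/max pooling of magnitudes.
    """
    X = np.asarray(map2d, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DegenerateInputError(
            f"spatial gradient needs a grid of at least 2x2, got {X.shape}"
        )
    H = np.zeros_like(X)
    V = np.zeros_like(X)
    H[:, :-1] = X[:, 1:] - X[:, :-1]
    V[:-1, :] = X[1:, :] - X[:-1, :]
    return H, V


def gradient_magnitude(H: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean norm of the gradient 2-vector [H, V]."""
    H = np.asarray(H, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if H.shape != V.shape:
        raise ValidationError(f"H shape {H.shape} != V shape {V.shape}")
    return np.hypot(H, V)


def gradient_stack(f: FeatureStack) -> GradientStack:
    """Gradients + magnitudes for every map in the stack."""
    Hs, Vs, Ms = [], [], []
    for k in range(f.n_maps):
        H, V = spatial_gradient(f.maps[k])
        Hs.append(H)
        Vs.append(V)
        Ms.append(gradient_magnitude(H, V))
    return GradientStack(H=np.stack(Hs), V=np.stack(Vs), magnitude=np.stack(Ms))


def pool_gradient_weights(g: GradientStack) -> PooledWeights:
    """Reduce each magnitude map to (average, global max) importance weights.

    Pooling the (n_maps, s, s) magnitude tensor into two length-n vectors is
    what makes the per-map weighting cheap: each map gets a scalar measure
    of how much sharp structure it contains.
    """
    if g.magnitude.size == 0:
        raise ValidationError("empty gradient stack")
    return PooledWeights(
        mean_vec=g.magnitude.mean(axis=(1, 2)),
        max_vec=g.magnitude.max(axis=(1, 2)),
    )


def weight_feature_maps(
    f: FeatureStack, w: PooledWeights, combine: str = "product"
) -> FeatureStack:
    """Component-wise re-weighting: map k scaled by its pooled weight(s).

    ``combine='product'`` (default) multiplies map k by
    ``mean_vec[k] * max_vec[k]`` so both pooled vectors act and the output
    is still exactly one stack of 32 maps.  ``combine='sum'`` uses
    ``mean_vec[k] + max_vec[k]`` instead.
    """
    if len(w.mean_vec) != f.n_maps:
        raise ValidationError(
            f"{len(w.mean_vec)} weights for {f.n_maps} feature maps"
        )
    if combine == "product":
        wk = w.mean_vec * w.max_vec
    elif combine == "sum":
        wk = w.mean_vec + w.max_vec
    else:
        raise ConfigurationError(f"unknown combine rule {combine!r}")
    return FeatureStack(maps=f.maps * wk[:, None, None])


def mean_saliency(f: FeatureStack) -> np.ndarray:
    """Per-pixel arithmetic mean over the (weighted) maps."""
    if f.n_maps == 0:
        raise ValidationError("empty feature stack")
    return f.maps.mean(axis=0)


def normalize_to_grayscale(m: np.ndarray) -> SaliencyMap:
    """Clamp negatives to 0, then scale so the global max is 1.

    An all-zero (or all-negative) input maps to all-zero output rather than
    dividing by zero.
    """
    m = np.asarray(m, dtype=np.float64)
    if not np.isfinite(m).all():
        raise ValidationError("saliency input contains non-finite values")
    m = np.clip(m, 0.0, None)
    peak = m.max()
    if peak > 0:
        m = m / peak
    return SaliencyMap(gray=m, source_shape=m.shape)


def upsample_saliency(
    m: SaliencyMap, target_shape: tuple[int, int]
) -> SaliencyMap:
    """Bilinear upsample to slice resolution; values stay in [0, 1]."""
    if target_shape[0] < m.gray.shape[0] or target_shape[1] < m.gray.shape[1]:
        raise ValidationError(
            f"target {target_shape} smaller than source {m.gray.shape}"
        )
    if tuple(target_shape) == m.gray.shape:
        return SaliencyMap(gray=m.gray.copy(), source_shape=m.gray.shape)
    up = resize(
        m.gray, target_shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return SaliencyMap(gray=np.clip(up, 0.0, 1.0), source_shape=m.gray.shape)


def apply_colormap(m: SaliencyMap) -> np.ndarray:
    """Jet colormap: (N, N) grayscale -> (N, N, 3) RGB in [0, 1]."""
    cmap = colormaps["jet"]
    return np.asarray(cmap(m.gray)[..., :3], dtype=np.float64)


def to_rgb(gray: np.ndarray) -> np.ndarray:
    """Replicate one channel to 3 for display, rescaled to [0, 1]."""
    g = np.asarray(gray, dtype=np.float64)
    lo, hi = g.min(), g.max()
    if hi > lo:
        g = (g - lo) / (hi - lo)
    else:
        g = np.zeros_like(g)
    return np.repeat(g[..., None], 3, axis=-1)


def superimpose(
    slice_rgb: np.ndarray, colormapped: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> np.ndarray:
    """Additive overlay slice + alpha * colormap, clipped to [0, 1]."""
    slice_rgb = np.asarray(slice_rgb, dtype=np.float64)
    colormapped = np.asarray(colormapped, dtype=np.float64)
    if slice_rgb.shape != colormapped.shape:
        raise ValidationError(
            f"image {slice_rgb.shape} and colormap {colormapped.shape} differ"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    return np.clip(slice_rgb + alpha * colormapped, 0.0, 1.0)


def threshold_mask(m: SaliencyMap, tau: float) -> SegMask:
    """Binary mask: 1 where gray >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise ValidationError("tau must lie in [0, 1]")
    return SegMask(
        mask=(m.gray >= tau).astype(np.uint8),
        threshold_used=float(tau),
        provenance="fixed",
    )


def threshold_sweep(
    m: SaliencyMap,
    ref: np.ndarray,
    taus: Sequence[float] = DEFAULT_TAUS,
    post_cfg: PostprocessConfig | None = None,
) -> tuple[float, SegMask, pd.DataFrame]:
    """Try every tau, score post-processed masks by Dice against ``ref``.

    Returns (best tau, its post-processed mask, per-tau table with columns
    tau / dsc_raw / dsc_post).  Ties break toward the smallest tau.  When no
    tau overlaps a non-empty reference the table carries an
    ``empty_overlap`` flag column set for every row.
    """
    if len(taus) == 0:
        raise ValidationError("tau list must be non-empty")
    ref = np.asarray(ref)
    if ref.shape != m.gray.shape:
        raise ValidationError(
            f"reference {ref.shape} not aligned with saliency {m.gray.shape}"
        )
    post_cfg = post_cfg or PostprocessConfig()
    rows = []
    best = None
    for tau in taus:
        raw = threshold_mask(m, float(tau))
        post = postprocess_mask(raw.mask, post_cfg)
        d_raw = dice(ref, raw.mask)
        d_post = dice(ref, post)
        rows.append({"tau": float(tau), "dsc_raw": d_raw, "dsc_post": d_post})
        if best is None or d_post > best[1]:  # strict: ties keep smallest tau
            best = (float(tau), d_post, post)
    table = pd.DataFrame(rows)
    table["empty_overlap"] = bool(table["dsc_post"].max() == 0.0)
    best_tau, _, best_mask = best
    return best_tau, SegMask(best_mask, best_tau, "sweep"), table


@dataclass
class SegmentationResult:
    """Everything the segmentation stage produces for one slice."""

    mask: SegMask                  # post-processed final mask
    raw_mask: SegMask              # same threshold, before post-processing
    saliency: SaliencyMap          # upsampled grayscale map
    overlay: np.ndarray            # RGB slice + jet saliency
    label: str
    score: float
    sweep_table: pd.DataFrame | None = None


def compute_saliency(
    feats: FeatureStack,
    target_shape: tuple[int, int],
    combine: str = "product",
) -> SaliencyMap:
    """Feature stack -> upsampled grayscale saliency (steps 1-6 minus the
    threshold)."""
    g = gradient_stack(feats)
    w = pool_gradient_weights(g)
    weighted = weight_feature_maps(feats, w, combine=combine)
    sal = normalize_to_grayscale(mean_saliency(weighted))
    return upsample_saliency(sal, target_shape)


def segment_slice(
    net: Network,
    s: Slice2D,
    mode: str = "fixed",
    ref: np.ndarray | None = None,
    tau_fixed: float = DEFAULT_FIXED_TAU,
    taus: Sequence[float] = DEFAULT_TAUS,
    post_cfg: PostprocessConfig | None = None,
    alpha: float = DEFAULT_ALPHA,
    combine: str = "product",
) -> SegmentationResult:
    """Classification gate, then the full saliency -> mask -> overlay chain.

    ``mode='sweep'`` needs a reference mask (evaluation use); ``mode='fixed'``
    thresholds at ``tau_fixed`` (mask-free deployment).  A slice classified
    as not-tumor raises :class:`NoTumorDetected` — the gate is explicit, not
    an empty mask.
    """
    if mode not in ("fixed", "sweep"):
        raise ConfigurationError(f"unknown segmentation mode {mode!r}")
    if mode == "sweep" and ref is None:
        raise ConfigurationError("sweep mode requires a reference mask")
    label, score, feats = classify(net, s)
    if label != "tumor":
        raise NoTumorDetected(
            f"slice classified as '{label}' (score {score:.3f}); nothing to segment"
        )
    post_cfg = post_cfg or PostprocessConfig()
    sal = compute_saliency(feats, s.shape, combine=combine)

    sweep_table = None
    if mode == "sweep":
        best_tau, mask, sweep_table = threshold_sweep(sal, ref, taus, post_cfg)
        raw = threshold_mask(sal, best_tau)
    else:
        raw = threshold_mask(sal, tau_fixed)
        mask = SegMask(postprocess_mask(raw.mask, post_cfg), tau_fixed, "fixed")

    overlay = superimpose(to_rgb(s.pixels), apply_colormap(sal), alpha=alpha)
    return SegmentationResult(
        mask=mask,
        raw_mask=raw,
        saliency=sal,
        overlay=overlay,
        label=label,
        score=score,
        sweep_table=sweep_table,
    )
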