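"""Synthetic FLAIR-like phantom slices with exact ground truth.

Each phantom is a 2D axial "slice": an elliptical bright brain region with
smooth low-frequency texture plus pixel noise on a zero background, and —
with configurable probability — one compact hyperintense lesion (an ellipse
with a Gaussian-smoothed edge) placed inside the brain.  The lesion emulates
the appearance of whole tumor plus peritumoral edema on FLAIR: the brightest
structure in the slice.  The paired binary mask is the lesion's support, so
segmentation can be scored exactly; the slice label (tumor / not tumor)
derives from the mask the same way real slices are labeled from expert
segmentations.

Generation is bit-reproducible from (spec, seed): every per-item RNG is
derived from the master seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .io_slices import MRIVolume, Modality, Slice2D, save_nifti_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "export_phantom_nifti"]


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the simulated slice.

    Intensities are arbitrary units with brain tissue near 1.0.  The lesion's
    mean is ``tissue mean + lesion_contrast * tissue std``, so contrast is in
    units of the within-brain intensity spread — contrast 3 is a conspicuous
    FLAIR-like lesion, contrast 1 barely rises above texture.
    """

    side: int = 128
    tumor_prob: float = 0.5
    lesion_radius_range: tuple[int, int] = (6, 20)
    lesion_contrast: float = 3.0
    tissue_noise_sigma: float = 0.05   # per-pixel noise, intensity units
    texture_sigma: float = 0.08        # amplitude of the smooth texture field
    blur_sigma: float = 1.0            # px; edge smoothing of brain and lesion
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < self.side // 2):
            raise ValidationError("lesion radius range must fit inside the image")
        if not 0.0 <= self.tumor_prob <= 1.0:
            raise ValidationError("tumor_prob must be a probability")
        if self.lesion_contrast <= 0:
            raise ValidationError("lesion_contrast must be > 0")
        if min(self.tissue_noise_sigma, self.texture_sigma, self.blur_sigma) < 0:
            raise ValidationError("noise/texture/blur sigmas must be >= 0")

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "tumor_prob": self.tumor_prob,
            "lesion_radius_range": list(self.lesion_radius_range),
            "lesion_contrast": self.lesion_contrast,
            "tissue_noise_sigma": self.tissue_noise_sigma,
            "texture_sigma": self.texture_sigma,
            "blur_sigma": self.blur_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "lesion_radius_range" in d:
            d["lesion_radius_range"] = tuple(d["lesion_radius_range"])
        return cls(**d)


def _ellipse_mask(
    side: int, center: tuple[float, float], radii: tuple[float, float], angle: float
) -> np.ndarray:
    """Boolean support of a rotated ellipse on a side x side grid."""
    rr, cc = np.mgrid[0:side, 0:side]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[Slice2D, np.ndarray, int]:
    """One phantom: (slice, binary lesion mask, tumor label).

    The brain ellipse spans ~70-85% of the image side; its interior is
    base intensity 1.0 modulated by a smooth random texture field plus
    per-pixel Gaussian noise.  With probability ``tumor_prob`` a lesion
    ellipse (radii drawn from ``lesion_radius_range``) is placed with its
    center well inside the brain, raised to
    tissue mean + lesion_contrast * tissue std, and blended with a
    Gaussian-smoothed edge.  Label = 1 iff the mask is non-empty.
    """
    side = spec.side
    # brain ellipse: centered, mild anisotropy and tilt
    brain_radii = (
        side / 2 * rng.uniform(0.70, 0.85),
        side / 2 * rng.uniform(0.70, 0.85),
    )
    brain_angle = rng.uniform(0, np.pi)
    brain = _ellipse_mask(side, (side / 2, side / 2), brain_radii, brain_angle)

    # smooth interior texture: low-frequency Gaussian random field
    texture = gaussian_filter(rng.normal(0.0, 1.0, (side, side)), sigma=side / 16)
    tex_std = texture.std()
    if tex_std > 0:
        texture = texture / tex_std * spec.texture_sigma

    image = np.zeros((side, side), dtype=np.float64)
    image[brain] = 1.0 + texture[brain]
    # soften the brain boundary so the rim is not a step edge
    if spec.blur_sigma > 0:
        image = gaussian_filter(image, sigma=spec.blur_sigma)

    mask = np.zeros((side, side), dtype=np.uint8)
    has_tumor = rng.random() < spec.tumor_prob
    if has_tumor:
        tissue_mean = float(image[brain].mean())
        tissue_std = float(image[brain].std())
        lo, hi = spec.lesion_radius_range
        radii = (rng.uniform(lo, hi), rng.uniform(lo, hi))
        angle = rng.uniform(0, np.pi)
        rmax = max(radii)
        # center placed so the whole lesion stays inside the brain ellipse
        for _ in range(100):
            t = rng.uniform(0, 2 * np.pi)
            rho = rng.uniform(0, 0.9)
            center = (
                side / 2 + rho * (brain_radii[0] - rmax) * np.cos(t),
                side / 2 + rho * (brain_radii[1] - rmax) * np.sin(t),
            )
            lesion = _ellipse_mask(side, center, radii, angle)
            if (lesion & ~brain).sum() == 0 and lesion.any():
                break
        mask = lesion.astype(np.uint8)
        lesion_level = tissue_mean + spec.lesion_contrast * tissue_std
        soft = lesion.astype(np.float64)
        if spec.blur_sigma > 0:
            soft = gaussian_filter(soft, sigma=spec.blur_sigma)
        image = image * (1 - soft) + lesion_level * soft

    if spec.tissue_noise_sigma > 0:
        image = image + rng.normal(0.0, spec.tissue_noise_sigma, (side, side))

    label = int(mask.any())
    sl = Slice2D(pixels=image, modality=Modality.FLAIR, volume_id="phantom")
    return sl, mask, label


def generate_dataset(
    n: int, spec: PhantomSpec, seed: int | None = None
) -> dict:
    """``n`` phantoms with per-item seeds spawned from the master seed.

    Returns dict with ``slices``, ``masks``, ``labels``, ``seeds``.  Item i
    is generated from ``np.random.default_rng([master_seed, i])`` so any
    item can be regenerated in isolation.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    master = spec.seed if seed is None else seed
    slices: list[Slice2D] = []
    masks: list[np.ndarray] = []
    labels: list[int] = []
    seeds: list[list[int]] = []
    for i in range(n):
        rng = np.random.default_rng([master, i])
        sl, mask, label = generate_phantom(spec, rng)
        sl.volume_id = f"phantom-{master}-{i:05d}"
        slices.append(sl)
        masks.append(mask)
        labels.append(label)
        seeds.append([master, i])
    return {
        "slices": slices,
        "masks": masks,
        "labels": np.asarray(labels, dtype=int),
        "seeds": seeds,
        "spec": spec,
    }


def export_phantom_nifti(dataset: dict, directory: str | Path) -> Path:
    """Write each phantom as a single-slice NIfTI pair (image + mask) plus a
    CSV manifest (path, mask path, seed, label, lesion area in px).

    The exported files round-trip through ``io_slices.load_nifti_volume``,
    closing the loop for end-to-end tests without any external download.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    rows = []
    for sl, mask, label, seed in zip(
        dataset["slices"], dataset["masks"], dataset["labels"], dataset["seeds"]
    ):
        stem = sl.volume_id or f"phantom-{seed[0]}-{seed[1]:05d}"
        img_path = directory / f"{stem}_flair.nii.gz"
        msk_path = directory / f"{stem}_seg.nii.gz"
        save_nifti_volume(
            MRIVolume(sl.pixels[:, :, None], Modality.FLAIR, source_id=stem), img_path
        )
        save_nifti_volume(
            MRIVolume(
                mask.astype(np.float64)[:, :, None], Modality.SEG, source_id=stem
            ),
            msk_path,
        )
        rows.append(
            {
                "image": img_path.name,
                "mask": msk_path.name,
                "seed": f"{seed[0]}:{seed[1]}",
                "label": int(label),
                "lesion_area_px": int(mask.sum()),
            }
        )
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image", "mask", "seed", "label", "lesion_area_px"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path
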