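"""NIfTI volume loading and 2D slice extraction.

The working unit of the whole pipeline is a single axial FLAIR slice.  This
module reads a NIfTI volume, pulls out one axial plane (slice 90 of a
155-slice BraTS volume by default), crops it to the 192x152 brain window and
resizes it to the square geometry the classifier expects (128x128).

Volumes are kept in their native orientation; no registration, bias-field
correction or resampling is done here because BraTS volumes arrive already
co-registered and resampled to 1 mm isotropic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize

from .errors import BoundsError, FormatError, ValidationError

#: BraTS 2017 volumes are 240 x 240 x 155 after the challenge's own preprocessing.
BRATS_SHAPE = (240, 240, 155)

#: Axial plane used throughout: slice 90 (0-based) of 0..154.
DEFAULT_SLICE_INDEX = 90

#: Crop window that drops the empty margins around the brain.
DEFAULT_CROP = (192, 152)

#: Side of the square network input.
DEFAULT_INPUT_SIDE = 128


class Modality(str, enum.Enum):
    """MRI pulse sequence of a volume, plus SEG for label volumes."""

    T1 = "T1"
    T1C = "T1c"
    T2 = "T2"
    FLAIR = "FLAIR"
    SEG = "SEG"


@dataclass
class MRIVolume:
    """A 3D scalar volume with its acquisition metadata.

    ``brats_conformant`` is False for shapes other than 240x240x155; such
    volumes are accepted (phantom exports are single-slice) but flagged.
    """

    voxels: np.ndarray
    modality: Modality
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_id: str = ""
    brats_conformant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"volume must be 3-dimensional, got shape {self.voxels.shape}"
            )
        n_bad = int(np.size(self.voxels) - np.isfinite(self.voxels).sum())
        if n_bad:
            raise ValidationError(f"volume contains {n_bad} non-finite voxels")
        self.brats_conformant = self.voxels.shape == BRATS_SHAPE

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]


@dataclass
class Slice2D:
    """One axial plane with provenance back to its source volume."""

    pixels: np.ndarray
    modality: Modality = Modality.FLAIR
    volume_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"slice must be 2-dimensional, got shape {self.pixels.shape}"
            )
        if not np.isfinite(self.pixels).all():
            raise ValidationError("slice contains non-finite pixels")
        if self.slice_index < 0:
            raise ValidationError("slice_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Slice2D":
        """Copy provenance onto a new pixel grid."""
        return Slice2D(
            pixels=pixels,
            modality=self.modality,
            volume_id=self.volume_id,
            slice_index=self.slice_index,
        )


def load_nifti_volume(path: str | Path, modality: Modality | str) -> MRIVolume:
    """Read a NIfTI (.nii / .nii.gz) file into an :class:`MRIVolume`.

    Raises FileNotFoundError for a missing path, :class:`FormatError` when
    the file is not parseable NIfTI, and :class:`ValidationError` (naming
    the count) when the volume contains NaN/inf voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    if isinstance(modality, str):
        modality = Modality(modality)
    try:
        img = nib.load(path)
        voxels = np.asarray(img.dataobj, dtype=np.float64)
    except (nib.filebasedimages.ImageFileError, OSError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    return MRIVolume(
        voxels=voxels,
        modality=modality,
        spacing=tuple(float(z) for z in zooms),
        source_id=path.name,
    )


def save_nifti_volume(vol: MRIVolume, path: str | Path) -> Path:
    """Write a volume back out as NIfTI-1 with its spacing in the affine."""
    path = Path(path)
    affine = np.diag([*vol.spacing, 1.0])
    nib.save(nib.Nifti1Image(vol.voxels, affine), path)
    return path


def extract_slice(vol: MRIVolume, index: int = DEFAULT_SLICE_INDEX) -> Slice2D:
    """Return the axial plane ``vol.voxels[:, :, index]``.

    Raises :class:`BoundsError` when ``index`` is outside 0..n_slices-1.
    """
    if not 0 <= index < vol.n_slices:
        raise BoundsError(
            f"slice index {index} out of range for volume with {vol.n_slices} slices"
        )
    return Slice2D(
        pixels=vol.voxels[:, :, index].copy(),
        modality=vol.modality,
        volume_id=vol.source_id,
        slice_index=index,
    )


def crop_slice(
    s: Slice2D, rows: int = DEFAULT_CROP[0], cols: int = DEFAULT_CROP[1]
) -> Slice2D:
    """Centered rows x cols window of the slice (no interpolation).

    The brain sits in the middle of BraTS planes, so a centered window keeps
    it while dropping empty background. Raises :class:`BoundsError` if the
    requested window exceeds the slice.
    """
    r, c = s.shape
    if rows > r or cols > c:
        raise BoundsError(f"crop {rows}x{cols} larger than slice {r}x{c}")
    if rows < 1 or cols < 1:
        raise BoundsError("crop window must be at least 1x1")
    r0 = (r - rows) // 2
    c0 = (c - cols) // 2
    return s.with_pixels(s.pixels[r0 : r0 + rows, c0 : c0 + cols].copy())


def resize_to_input(s: Slice2D, side: int = DEFAULT_INPUT_SIDE) -> Slice2D:
    """Bilinear resample to the square ``side x side`` network geometry.

    A no-op (bit-identical) when the slice already has that shape.  Bilinear
    interpolation keeps values inside the input's [min, max] envelope.
    """
    if side < 8:
        raise BoundsError(f"network input side must be >= 8, got {side}")
    if s.shape == (side, side):
        return s.with_pixels(s.pixels.copy())
    out = resize(
        s.pixels,
        (side, side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return s.with_pixels(out)
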