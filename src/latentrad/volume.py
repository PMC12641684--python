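"""In-memory containers for 3D volumes and lesion masks, with NIfTI-1 I/O.

An :class:`ImageVolume` pairs a 3D intensity array with its voxel spacing
(mm per edge) and a voxel-to-world affine; a :class:`LesionMask` is a binary
array on the same grid.  Resampling and intensity normalisation mirror the
standard preprocessing of CT segmentation pipelines: trilinear interpolation
for intensities, nearest-neighbour for masks, and window-clipped z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


def spacing_affine(spacing_mm) -> np.ndarray:
    """Diagonal voxel-to-world affine for a given spacing."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class ImageVolume:
    """A 3D intensity image with voxel spacing metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (Hounsfield-like units for CT-style images).
    spacing_mm : tuple of 3 floats
        Voxel edge lengths in millimetres, per axis.
    affine : ndarray (4, 4), optional
        Voxel-to-world map; defaults to a diagonal affine built from the
        spacing.
    """

    data: np.ndarray
    spacing_mm: tuple
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")
        if self.affine is None:
            self.affine = spacing_affine(self.spacing_mm)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj).astype(np.float64), spacing, img.affine)


@dataclass
class LesionMask:
    """A binary lesion mask aligned to an :class:`ImageVolume` grid."""

    data: np.ndarray
    spacing_mm: tuple
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = arr.astype(bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = spacing_affine(self.spacing_mm)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        """Mask volume in millilitres (voxel count x voxel volume / 1000)."""
        return self.voxel_count * float(np.prod(self.spacing_mm)) / 1000.0

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @classmethod
    def load(cls, path) -> "LesionMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj) > 0.5, spacing, img.affine)


def resample_isotropic(vol, target_mm: float, is_mask: bool = False):
    """Resample a volume (or mask) to isotropic voxel spacing.

    Intensities are interpolated trilinearly; masks use nearest-neighbour so
    the output stays binary.  Returns the same container type as the input.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    factors = tuple(s / float(target_mm) for s in vol.spacing_mm)
    order = 0 if is_mask else 1
    data = vol.data.astype(np.float64) if not is_mask else vol.data.astype(np.uint8)
    out = ndimage.zoom(data, factors, order=order, mode="nearest", grid_mode=True)
    spacing = (float(target_mm),) * 3
    if is_mask:
        return LesionMask(out > 0.5, spacing)
    return ImageVolume(out, spacing)


def normalize_intensity(vol: ImageVolume, clip_lo: float = 0.0, clip_hi: float = 100.0) -> ImageVolume:
    """Clip to an intensity window, then z-score with the in-window mean/sd.

    A constant (zero-spread) input maps to all zeros rather than dividing by
    zero.  The default window [0, 100] is a soft-tissue analogue for brain-CT
    style intensities.
    """
    if clip_lo >= clip_hi:
        raise ValueError("clip_lo must be < clip_hi")
    clipped = np.clip(vol.data.astype(np.float64), clip_lo, clip_hi)
    mu = clipped.mean()
    sd = clipped.std()
    if sd == 0:
        out = np.zeros_like(clipped)
    else:
        out = (clipped - mu) / sd
    return ImageVolume(out, vol.spacing_mm, vol.affine)
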