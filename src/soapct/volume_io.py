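"""Volume and mask containers plus NIfTI / MetaImage I/O.

Arrays are indexed ``[x, y, z]`` with z the block long axis (the shot
direction).  Physical position of voxel ``(i, j, k)`` is
``origin_mm + (i, j, k) * spacing_mm`` (voxel-center convention, 0-based
indices).  NIfTI is handled by nibabel and MetaImage by SimpleITK; spacing
is always taken from the file header, never defaulted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import SimpleITK as sitk

__all__ = ["VoxelVolume", "BinaryMask", "read_volume", "write_volume",
           "read_mask", "write_mask"]

HU_MIN, HU_MAX = -2048.0, 32767.0


def _check_grid(shape, spacing, origin):
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if len(shape) != 3 or min(shape) < 1:
        raise ValueError("grid must be non-empty and 3D")
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be three strictly positive floats")
    if origin.shape != (3,):
        raise ValueError("origin must be three floats")
    return spacing, origin


@dataclass
class VoxelVolume:
    """3D scalar intensity grid in Hounsfield units with spacing metadata."""

    intensities: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        self.spacing_mm, self.origin_mm = _check_grid(
            self.intensities.shape, self.spacing_mm, self.origin_mm)
        lo, hi = float(self.intensities.min()), float(self.intensities.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"intensities outside the plausible HU range "
                f"[{HU_MIN:g}, {HU_MAX:g}]: found [{lo:g}, {hi:g}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def index_to_mm(self, idx) -> np.ndarray:
        """Physical coordinates (mm) of voxel index/indices (voxel centers)."""
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm


@dataclass
class BinaryMask:
    """Voxel-aligned segmentation sharing a :class:`VoxelVolume`'s grid.

    ``bits`` is boolean for single-region masks or a small-int label map
    for multi-region segmentations (0 = background).
    """

    bits: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not (self.bits.dtype == bool or np.issubdtype(self.bits.dtype, np.integer)):
            raise ValueError("mask dtype must be boolean or integer labels")
        self.spacing_mm, self.origin_mm = _check_grid(
            self.bits.shape, self.spacing_mm, self.origin_mm)

    @classmethod
    def like(cls, volume: VoxelVolume, bits: np.ndarray) -> "BinaryMask":
        bits = np.asarray(bits)
        if bits.shape != volume.shape:
            raise ValueError(
                f"mask shape {bits.shape} does not match parent volume "
                f"shape {volume.shape}")
        return cls(bits, volume.spacing_mm.copy(), volume.origin_mm.copy())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bits.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def check_same_grid(self, other) -> None:
        if self.shape != other.shape:
            raise ValueError("masks/volumes are not on the same grid (shape)")
        if not np.allclose(self.spacing_mm, other.spacing_mm):
            raise ValueError("masks/volumes are not on the same grid (spacing)")


_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


def _fmt(path: str) -> str:
    p = str(path).lower()
    if p.endswith(_NIFTI_EXT):
        return "nifti"
    if p.endswith(_META_EXT):
        return "meta"
    raise ValueError(
        f"unknown volume format for {path!r}: expected one of "
        f"{_NIFTI_EXT + _META_EXT}")


def _read(path: str):
    fmt = _fmt(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "nifti":
        try:
            img = nib.load(path)
            data = np.asarray(img.dataobj)
        except Exception as exc:
            raise ValueError(f"failed to read NIfTI file {path!r}: {exc}") from exc
        zooms = img.header.get_zooms()[:3]
        if len(zooms) != 3 or any(z <= 0 for z in zooms):
            raise ValueError(f"NIfTI file {path!r} carries no valid voxel spacing")
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return data, np.asarray(zooms, dtype=float), origin
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise ValueError(f"failed to read MetaImage file {path!r}: {exc}") from exc
    # SimpleITK arrays come back [z, y, x]; transpose to our [x, y, z]
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"MetaImage file {path!r} carries no valid voxel spacing")
    origin = np.asarray(img.GetOrigin(), dtype=float)
    return data, spacing, origin


def _write(data: np.ndarray, spacing, origin, path: str) -> None:
    fmt = _fmt(path)
    if fmt == "nifti":
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(data, affine), path)
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, str(path))


def read_volume(path) -> VoxelVolume:
    """Read a CT volume (NIfTI ``.nii``/``.nii.gz`` or MetaImage ``.mha``/``.mhd``)."""
    data, spacing, origin = _read(str(path))
    return VoxelVolume(data.astype(np.float32, copy=False), spacing, origin)


def write_volume(volume: VoxelVolume, path) -> None:
    """Write a volume; format chosen by extension."""
    _write(volume.intensities.astype(np.float32, copy=False),
           volume.spacing_mm, volume.origin_mm, str(path))


def write_mask(mask: BinaryMask, path, parent: VoxelVolume | None = None) -> None:
    """Write a mask losslessly as unsigned 8- or 16-bit labels.

    If ``parent`` is given the mask's grid is checked against it first.
    """
    if parent is not None:
        mask.check_same_grid(parent)
    labels = mask.bits.astype(np.uint16 if mask.bits.dtype != bool
                              and mask.bits.max(initial=0) > 255 else np.uint8)
    _write(labels, mask.spacing_mm, mask.origin_mm, str(path))


def read_mask(path) -> BinaryMask:
    """Read a mask written by :func:`write_mask` (labels preserved)."""
    data, spacing, origin = _read(str(path))
    if not np.issubdtype(np.asarray(data).dtype, np.integer):
        data = np.rint(data).astype(np.uint16)
    return BinaryMask(data, spacing, origin)
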