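"""Image and mask containers on axis-aligned voxel grids.

The whole pipeline works on scanner-native, axis-aligned grids: world
coordinates are ``origin + spacing * index`` (mm), with 0-based voxel
indices.  Images are stored index-ordered ``data[i, j, k]`` (x, y, z), the
same layout nibabel uses; conversion to SimpleITK (which stores z-fastest
arrays) is handled here so no other module needs to care.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
]


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def world_center(self) -> np.ndarray:
        """World coordinates of the grid centre (mm)."""
        idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return np.asarray(self.origin) + np.asarray(self.spacing) * idx

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T).astype(np.float64))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        arr = sitk.GetArrayFromImage(img).T
        return cls(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


@dataclass
class BinaryMask:
    """A 3D boolean segmentation aligned to an :class:`ImageVolume` grid.

    ``compartment`` records which tumor compartment the mask delineates:
    ``"CV"`` (gadolinium contrast-enhancing volume) or ``"FV"``
    (FLAIR-hyperintense tumor-related volume).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    compartment: str = "CV"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.grid.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def volume_ml(self) -> float:
        """Volume in ml: exact voxel count times the voxel volume."""
        return int(self.grid.sum()) * self.voxel_volume_mm3 / 1000.0

    def same_grid_as(self, other: "BinaryMask | ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "BinaryMask":
        return replace(self, grid=self.grid.copy())

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.grid.T).astype(np.uint8))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, compartment: str = "CV") -> "BinaryMask":
        arr = sitk.GetArrayFromImage(img).T
        return cls(arr > 0, tuple(img.GetSpacing()), tuple(img.GetOrigin()), compartment)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_image(vol: ImageVolume, path: str) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing, vol.origin)), path)


def load_image(path: str) -> ImageVolume:
    img = nib.load(path)
    aff = img.affine
    spacing = tuple(np.abs(np.diag(aff)[:3]))
    origin = tuple(aff[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float32), spacing, origin)


def save_mask(mask: BinaryMask, path: str) -> None:
    nib.save(
        nib.Nifti1Image(mask.grid.astype(np.uint8), _affine(mask.spacing, mask.origin)), path
    )


def load_mask(path: str, compartment: str = "CV") -> BinaryMask:
    img = nib.load(path)
    aff = img.affine
    spacing = tuple(np.abs(np.diag(aff)[:3]))
    origin = tuple(aff[:3, 3])
    return BinaryMask(np.asarray(img.dataobj) > 0, spacing, origin, compartment)
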