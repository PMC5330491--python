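"""Semi-automated two-plane seeded region-growing segmentation.

The workflow mirrors how a rater segments a tumor with a smart-brush style
tool: a 2D region is drawn on one axial slice and another on one coronal
slice; the tool grows these seeds into a rough 3D mask, which the rater
then corrects by adding or erasing voxels.

The growing algorithm here is deliberately simple and fully documented
(commercial tools of this kind are proprietary): the seed voxels define an
intensity tolerance band ``mean ± k·sd`` (inclusive bounds), the band is
grown by face-connected (6-neighbourhood by default) flood fill from the
seed regions, and a radius-1 morphological closing smooths the result into
a rough 3D interpolation.  Necrotic areas, cavities and vessels are kept
out by the band itself plus manual editing, not by a dedicated classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, ImageVolume

__all__ = [
    "SeedContour",
    "SegmentationError",
    "RunawayGrowthError",
    "segment_semiauto",
    "manual_edit",
    "mask_volume_ml",
    "seeds_from_mask",
]


class SegmentationError(ValueError):
    """Invalid segmentation input (empty or out-of-bounds seeds)."""


class RunawayGrowthError(RuntimeError):
    """Region growth exceeded the configured volume cap (tolerance too loose)."""


@dataclass
class SeedContour:
    """A 2D seed region on a single axial or coronal slice.

    With index order ``(x, y, z)``, an axial contour lives on a fixed-``z``
    slice (region shape ``(nx, ny)``) and a coronal contour on a fixed-``y``
    slice (region shape ``(nx, nz)``).
    """

    plane: str  # "axial" | "coronal"
    slice_index: int
    region: np.ndarray

    def __post_init__(self) -> None:
        if self.plane not in ("axial", "coronal"):
            raise SegmentationError(f"plane must be 'axial' or 'coronal', got {self.plane!r}")
        self.region = np.asarray(self.region).astype(bool)
        if self.region.ndim != 2:
            raise SegmentationError("seed region must be a 2D boolean grid")
        if not self.region.any():
            raise SegmentationError("seed region is empty")

    def to_volume_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        nx, ny, nz = shape
        out = np.zeros(shape, dtype=bool)
        if self.plane == "axial":
            if not 0 <= self.slice_index < nz:
                raise SegmentationError("axial slice_index outside grid")
            if self.region.shape != (nx, ny):
                raise SegmentationError("axial seed region shape mismatch")
            out[:, :, self.slice_index] = self.region
        else:
            if not 0 <= self.slice_index < ny:
                raise SegmentationError("coronal slice_index outside grid")
            if self.region.shape != (nx, nz):
                raise SegmentationError("coronal seed region shape mismatch")
            out[:, self.slice_index, :] = self.region
        return out


_STRUCTS = {6: ndimage.generate_binary_structure(3, 1),
            18: ndimage.generate_binary_structure(3, 2),
            26: ndimage.generate_binary_structure(3, 3)}


def segment_semiauto(
    image: ImageVolume,
    axial_seed: SeedContour,
    coronal_seed: SeedContour,
    tolerance_k: float = 2.5,
    connectivity: int = 6,
    closing_radius: int = 1,
    volume_cap_ml: float | None = None,
    compartment: str = "CV",
    min_band_halfwidth: float = 1e-9,
) -> BinaryMask:
    """Grow the two seed contours into a 3D tumor mask.

    The intensity band is ``seed mean ± tolerance_k * seed sd`` (inclusive);
    the mask is the union of the band's connected components that touch a
    seed voxel, closed morphologically with ``closing_radius`` (set it to 0
    to get the pure in-band flood-fill result).  ``volume_cap_ml`` guards
    against runaway growth into the background when the band is too loose.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    seed_vol = axial_seed.to_volume_mask(image.shape) | coronal_seed.to_volume_mask(image.shape)

    vals = image.data[seed_vol]
    mean = float(vals.mean())
    sd = float(vals.std())
    half = max(tolerance_k * sd, min_band_halfwidth)
    band = (image.data >= mean - half) & (image.data <= mean + half)
    if not band[seed_vol].any():
        raise SegmentationError("no seed voxel lies inside its own tolerance band")

    labels, _ = ndimage.label(band, structure=_STRUCTS[connectivity])
    keep = np.unique(labels[seed_vol & band])
    keep = keep[keep != 0]
    mask = np.isin(labels, keep)

    if closing_radius > 0:
        ball = _ball(closing_radius)
        mask = ndimage.binary_closing(mask, structure=ball)
    mask |= seed_vol  # seeds always contained

    out = BinaryMask(mask, image.spacing, image.origin, compartment)
    if volume_cap_ml is not None and out.volume_ml > volume_cap_ml:
        raise RunawayGrowthError(
            f"grown volume {out.volume_ml:.1f} ml exceeds cap {volume_cap_ml:.1f} ml; "
            "the intensity tolerance is probably too loose"
        )
    return out


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r * r


def manual_edit(mask: BinaryMask, add=None, erase=None) -> BinaryMask:
    """Rater correction: ``(mask ∪ add) \\ erase``.

    ``add``/``erase`` may be boolean volumes of the mask's shape or
    iterables of ``(i, j, k)`` voxel indices.  Empty edits return an
    identical copy.
    """
    grid = mask.grid.copy()
    for voxels, value in ((add, True), (erase, False)):
        if voxels is None:
            continue
        sel = np.asarray(voxels)
        if sel.dtype == bool:
            if sel.shape != grid.shape:
                raise SegmentationError("edit volume shape mismatch")
            grid[sel] = value
        else:
            if sel.size == 0:
                continue
            sel = sel.reshape(-1, 3)
            if (sel < 0).any() or (sel >= np.asarray(grid.shape)).any():
                raise SegmentationError("edit voxel indices outside grid")
            grid[sel[:, 0], sel[:, 1], sel[:, 2]] = value
    return BinaryMask(grid, mask.spacing, mask.origin, mask.compartment)


def mask_volume_ml(mask: BinaryMask) -> float:
    """Mask volume in ml: exact voxel count times voxel volume (mm³)/1000."""
    return mask.volume_ml


def seeds_from_mask(mask: np.ndarray, erode: int = 1) -> tuple[SeedContour, SeedContour]:
    """Derive the rater's two seed contours from a reference mask.

    Emulates the manual step of drawing one axial and one coronal 2D region
    through the tumor: the largest-area axial and coronal slices of the
    reference mask, eroded to stay safely on foreground intensity.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise SegmentationError("reference mask is empty")
    z_areas = mask.sum(axis=(0, 1))
    y_areas = mask.sum(axis=(0, 2))
    z = int(np.argmax(z_areas))
    y = int(np.argmax(y_areas))
    ax_region = mask[:, :, z]
    co_region = mask[:, y, :]
    if erode > 0:
        er_ax = ndimage.binary_erosion(ax_region, iterations=erode)
        er_co = ndimage.binary_erosion(co_region, iterations=erode)
        ax_region = er_ax if er_ax.any() else ax_region
        co_region = er_co if er_co.any() else co_region
    return (
        SeedContour("axial", z, ax_region),
        SeedContour("coronal", y, co_region),
    )
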