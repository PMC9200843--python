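"""Image containers, spacing harmonization, resampling and gray-level
discretization.

Cohorts acquired on different scanners come with heterogeneous voxel
spacings; texture features are sensitive to this, so every image/mask pair
is resampled onto the component-wise minimum spacing of the cohort before
extraction (trilinear for intensities, nearest-neighbor for the mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "QuantizedROI",
    "compute_min_spacing",
    "resample_pair",
    "quantize",
]


@dataclass
class ImageVolume:
    """A 3D scalar image (e.g. CT in HU) on a regular grid.

    ``intensities`` is indexed ``[x, y, z]``; ``spacing`` and ``origin``
    are (x, y, z) in millimetres.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class SegmentationMask:
    """Binary segmentation aligned voxel-for-voxel with an :class:`ImageVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = (np.asarray(self.labels) > 0).astype(np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.labels.sum() < 1:
            raise ValueError("mask must contain at least one foreground voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.labels.sum())


@dataclass
class QuantizedROI:
    """In-mask gray levels mapped to integers ``1..n_levels``.

    ``levels`` carries level 0 outside the mask so that texture matrices can
    be computed directly on the 3D grid.
    """

    levels: np.ndarray        # int array, 0 outside mask, 1..n_levels inside
    bin_edges: np.ndarray
    n_levels: int
    mask: np.ndarray = field(repr=False, default=None)

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask > 0]


def compute_min_spacing(
    spacings: Iterable[Sequence[float]],
) -> tuple[float, float, float]:
    """Component-wise minimum voxel spacing across a cohort of scans."""
    arr = np.asarray(list(spacings), dtype=float)
    if arr.size == 0:
        raise ValueError("spacing collection is empty")
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("each spacing must be an (x, y, z) triplet")
    if np.any(arr <= 0):
        raise ValueError("all spacing components must be > 0")
    return tuple(float(v) for v in arr.min(axis=0))


def _to_sitk(array: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK indexes [z, y, x]; our arrays are [x, y, z]
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.T))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


def resample_pair(
    image: ImageVolume,
    mask: SegmentationMask,
    target: Sequence[float],
) -> tuple[ImageVolume, SegmentationMask]:
    """Resample an image/mask pair onto ``target`` spacing.

    Intensities are interpolated trilinearly, the mask with nearest
    neighbors so it stays binary.  The output grid covers the physical
    extent of the input.
    """
    target = tuple(float(t) for t in target)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be > 0, got {target}")

    in_size = image.intensities.shape
    in_spacing = image.spacing
    out_size = tuple(
        int(np.ceil(sz * sp / tg - 1e-9))
        for sz, sp, tg in zip(in_size, in_spacing, target)
    )
    if any(s < 2 for s in out_size):
        raise ValueError(
            f"target spacing {target} too coarse for extent: output size {out_size}"
        )

    def _resample(arr, interp):
        img = _to_sitk(arr, in_spacing, image.origin)
        res = sitk.Resample(
            img,
            out_size,
            sitk.Transform(),
            interp,
            img.GetOrigin(),
            target,
            img.GetDirection(),
            0.0,
            sitk.sitkFloat64,
        )
        return _from_sitk(res)

    new_int = _resample(image.intensities, sitk.sitkLinear)
    new_lab = _resample(mask.labels.astype(float), sitk.sitkNearestNeighbor)
    return (
        ImageVolume(new_int, target, image.origin),
        SegmentationMask(new_lab > 0.5, target, mask.origin),
    )


def quantize(
    image: ImageVolume | np.ndarray,
    mask: SegmentationMask | np.ndarray,
    n_levels: int = 32,
) -> QuantizedROI:
    """Discretize in-mask intensities into ``n_levels`` equal-width bins.

    Bins span the in-mask min..max; the maximum intensity maps to level
    ``n_levels``.  A constant region maps entirely to level 1.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    arr = image.intensities if isinstance(image, ImageVolume) else np.asarray(image, float)
    m = mask.labels if isinstance(mask, SegmentationMask) else (np.asarray(mask) > 0).astype(np.uint8)
    if m.sum() < 1:
        raise ValueError("mask is empty")

    vals = arr[m > 0]
    lo, hi = float(vals.min()), float(vals.max())
    edges = np.linspace(lo, hi, n_levels + 1)
    levels = np.zeros(arr.shape, dtype=np.int32)
    if hi == lo:
        levels[m > 0] = 1
    else:
        width = (hi - lo) / n_levels
        lv = np.floor((arr[m > 0] - lo) / width).astype(np.int32) + 1
        np.clip(lv, 1, n_levels, out=lv)
        levels[m > 0] = lv
    return QuantizedROI(levels=levels, bin_edges=edges, n_levels=n_levels, mask=m)
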