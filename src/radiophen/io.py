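"""NIfTI and CSV input/output for the pipeline.

CSV dialect: UTF-8, comma-separated, header row, sample id in the first
column.  Images and masks travel as NIfTI (.nii/.nii.gz) pairs on the
same grid.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features.preprocess import ImageVolume, SegmentationMask

__all__ = [
    "read_image_mask_pair",
    "write_image_mask_pair",
    "read_feature_table",
    "read_table",
]

_SPACING_TOL = 1e-3  # mm


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, spacing, origin


def read_image_mask_pair(
    image_path: str | Path, mask_path: str | Path
) -> tuple[ImageVolume, SegmentationMask]:
    """Load an aligned image/mask NIfTI pair; the mask is binarized at
    > 0.  Grid or spacing disagreement beyond 1e-3 mm is an error."""
    img_data, img_sp, img_or = _load_nifti(image_path)
    msk_data, msk_sp, msk_or = _load_nifti(mask_path)
    if img_data.shape != msk_data.shape:
        raise ValueError(
            f"grid mismatch: image {image_path} has shape {img_data.shape}, "
            f"mask {mask_path} has shape {msk_data.shape}"
        )
    if any(abs(a - b) > _SPACING_TOL for a, b in zip(img_sp, msk_sp)):
        raise ValueError(
            f"spacing mismatch beyond {_SPACING_TOL} mm: image {img_sp} vs "
            f"mask {msk_sp}"
        )
    return (
        ImageVolume(img_data, img_sp, img_or),
        SegmentationMask(msk_data > 0, img_sp, msk_or),
    )


def write_image_mask_pair(
    image: ImageVolume,
    mask: SegmentationMask,
    image_path: str | Path,
    mask_path: str | Path,
) -> None:
    for arr, sp, path in (
        (image.intensities, image.spacing, image_path),
        (mask.labels.astype(np.uint8), mask.spacing, mask_path),
    ):
        affine = np.diag(list(sp) + [1.0])
        out = nib.Nifti1Image(np.asarray(arr), affine)
        out.header.set_zooms(sp)
        nib.save(out, str(path))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns: {non_numeric}")
    return df
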