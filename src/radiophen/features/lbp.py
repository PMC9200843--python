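"""Slice-wise rotation-invariant uniform local binary patterns.

The operator works on 3x3 pixel blocks in each axial (z) slice: the center
pixel thresholds its 8 neighbors and the resulting code is mapped to the
10-bin rotation-invariant uniform alphabet.  Only centers whose full 3x3
neighborhood lies inside the mask contribute; the per-slice code histogram
is normalized and averaged over contributing slices.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.feature import local_binary_pattern

from .preprocess import ImageVolume, SegmentationMask

__all__ = ["lbp_features", "N_LBP_BINS"]

N_LBP_BINS = 10  # P=8 'uniform' (rotation-invariant) codes: 0..8 plus non-uniform


def lbp_features(
    image: ImageVolume | np.ndarray, mask: SegmentationMask | np.ndarray
) -> dict[str, float]:
    arr = image.intensities if isinstance(image, ImageVolume) else np.asarray(image, float)
    m = mask.labels if isinstance(mask, SegmentationMask) else (np.asarray(mask) > 0).astype(np.uint8)

    hists = []
    for z in range(arr.shape[2]):
        sl_mask = m[:, :, z]
        if sl_mask.sum() < 9:
            continue
        # eligible centers: full 3x3 neighborhood in-mask
        core = ndimage.binary_erosion(sl_mask, structure=np.ones((3, 3)))
        if not core.any():
            continue
        with warnings.catch_warnings():
            # CT slices are float-valued; the integer-dtype caveat about
            # near-tie pixels is acceptable here
            warnings.filterwarnings("ignore", message=".*floating-point images.*")
            codes = local_binary_pattern(arr[:, :, z], P=8, R=1, method="uniform")
        h = np.bincount(
            codes[core].astype(int), minlength=N_LBP_BINS
        ).astype(float)
        hists.append(h / h.sum())
    if not hists:
        raise ValueError("no axial slice contains a full 3x3 in-mask patch")
    mean_h = np.mean(hists, axis=0)
    return {f"lbp_bin_{i:02d}": float(mean_h[i]) for i in range(N_LBP_BINS)}
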