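"""First-order intensity statistics, discretized-histogram statistics and
intensity-volume histogram (IVH) features.

Moment conventions are population (biased) throughout; skewness and excess
kurtosis of a constant region are defined as 0.
"""

from __future__ import annotations

import numpy as np

from .preprocess import ImageVolume, QuantizedROI, SegmentationMask

__all__ = [
    "intensity_features",
    "histogram_features",
    "ivh_features",
    "first_order_and_histogram_features",
]


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """mean, population variance, skewness, excess kurtosis (0 if constant)."""
    mu = float(x.mean())
    var = float(((x - mu) ** 2).mean())
    if var == 0.0:
        return mu, 0.0, 0.0, 0.0
    sd = np.sqrt(var)
    skew = float((((x - mu) / sd) ** 3).mean())
    kurt = float((((x - mu) / sd) ** 4).mean() - 3.0)
    return mu, var, skew, kurt


def intensity_features(
    image: ImageVolume | np.ndarray, mask: SegmentationMask | np.ndarray
) -> dict[str, float]:
    arr = image.intensities if isinstance(image, ImageVolume) else np.asarray(image, float)
    m = mask.labels if isinstance(mask, SegmentationMask) else (np.asarray(mask) > 0)
    x = arr[m > 0].astype(float)
    if x.size == 0:
        raise ValueError("mask is empty")
    mu, var, skew, kurt = _moments(x)
    return {
        "int_mean": mu,
        "int_variance": var,
        "int_std": float(np.sqrt(var)),
        "int_skewness": skew,
        "int_kurtosis": kurt,
        "int_median": float(np.median(x)),
        "int_min": float(x.min()),
        "int_max": float(x.max()),
        "int_range": float(x.max() - x.min()),
        "int_energy": float((x**2).sum()),
        "int_rms": float(np.sqrt((x**2).mean())),
        "int_mad": float(np.abs(x - mu).mean()),
        "int_p10": float(np.percentile(x, 10)),
        "int_p90": float(np.percentile(x, 90)),
    }


def histogram_features(quantized: QuantizedROI) -> dict[str, float]:
    """Statistics of the discretized gray-level distribution.

    Entropy is in bits; uniformity is the sum of squared level
    probabilities (1 for a constant region, where entropy is 0).
    """
    lv = quantized.in_mask_levels.astype(float)
    counts = np.bincount(
        quantized.in_mask_levels, minlength=quantized.n_levels + 1
    )[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    mu, var, skew, kurt = _moments(lv)
    q75, q25 = np.percentile(lv, [75, 25])
    return {
        "hist_entropy": float(-(nz * np.log2(nz)).sum()),
        "hist_uniformity": float((p**2).sum()),
        "hist_mean": mu,
        "hist_variance": var,
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_median": float(np.median(lv)),
        "hist_mode": float(np.argmax(counts) + 1),
        "hist_min": float(lv.min()),
        "hist_max": float(lv.max()),
        "hist_range": float(lv.max() - lv.min()),
        "hist_iqr": float(q75 - q25),
        "hist_p10": float(np.percentile(lv, 10)),
        "hist_p90": float(np.percentile(lv, 90)),
    }


def first_order_and_histogram_features(
    image: ImageVolume | np.ndarray,
    mask: SegmentationMask | np.ndarray,
    quantized: QuantizedROI,
) -> dict[str, float]:
    out = intensity_features(image, mask)
    out.update(histogram_features(quantized))
    return out


def ivh_features(quantized: QuantizedROI) -> dict[str, float]:
    """Intensity-volume histogram features.

    Levels are mapped to intensity fractions gamma in [0, 1]; V(gamma) is
    the fraction of ROI volume at intensity fraction >= gamma (non-increasing
    in gamma), and I_x is the smallest achieved intensity fraction whose
    volume fraction is <= x%.  A constant region has gamma = 0 everywhere,
    V = 1 at every threshold and I_x = 0.
    """
    lv = quantized.in_mask_levels
    ng = quantized.n_levels
    if lv.max() > lv.min() and ng > 1:
        frac = (lv - 1) / (ng - 1)
    else:
        # constant region: every voxel sits at the (degenerate) maximum,
        # so the whole volume is above any threshold
        frac = np.ones(lv.shape)

    def v_at(gamma: float) -> float:
        return float((frac >= gamma).mean())

    def i_at(x_pct: float) -> float:
        # smallest achieved intensity fraction with volume fraction <= x%
        cand = np.unique(frac)
        for g in cand:
            if v_at(g) <= x_pct / 100.0:
                return float(g)
        return 0.0

    out: dict[str, float] = {}
    for p in (10, 20, 30, 40, 50, 60, 70, 80, 90):
        out[f"ivh_v{p}"] = v_at(p / 100.0)
    for p in (10, 25, 50, 75, 90):
        out[f"ivh_i{p}"] = i_at(p)
    out["ivh_v10_minus_v90"] = out["ivh_v10"] - out["ivh_v90"]
    out["ivh_i10_minus_i90"] = out["ivh_i10"] - out["ivh_i90"]
    return out
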