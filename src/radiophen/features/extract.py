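"""Full 102-feature extraction from a segmented tumor volume."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .. import manifest
from .firstorder import first_order_and_histogram_features, ivh_features
from .lbp import lbp_features
from .morphology import morphology_features
from .preprocess import ImageVolume, SegmentationMask, quantize, resample_pair
from .texture import DIRECTIONS_13, glrlm_features, glszm_features, ngtdm_features

__all__ = ["ExtractionConfig", "FeatureExtractionError", "extract_all", "extract_cohort"]


class FeatureExtractionError(RuntimeError):
    """Raised when a feature family fails; carries the family name."""


@dataclass
class ExtractionConfig:
    """Extraction settings.

    n_levels is the fixed number of equal-width gray-level bins used for
    the histogram, IVH and texture families; directions are the GLRLM
    displacement vectors (merged before feature computation).
    """

    n_levels: int = 32
    directions: Sequence[tuple[int, int, int]] = field(default=DIRECTIONS_13)
    target_spacing: tuple[float, float, float] | None = None
    manifest_version: str = manifest.MANIFEST_VERSION


def extract_all(
    image: ImageVolume,
    mask: SegmentationMask,
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Extract the full 102-feature vector from an aligned image/mask pair.

    If ``config.target_spacing`` is set the pair is resampled first.
    Returns an ordered mapping following the manifest; every value is
    finite and the computation is deterministic.
    """
    config = config or ExtractionConfig()
    if image.intensities.shape != mask.labels.shape:
        raise ValueError(
            f"image shape {image.intensities.shape} != mask shape {mask.labels.shape}"
        )
    if config.target_spacing is not None:
        image, mask = resample_pair(image, mask, config.target_spacing)

    quantized = quantize(image, mask, config.n_levels)
    values: dict[str, float] = {}

    stages = [
        ("intensity/histogram",
         lambda: first_order_and_histogram_features(image, mask, quantized)),
        ("volumetric", lambda: ivh_features(quantized)),
        ("morphologic", lambda: morphology_features(mask)),
        ("GLRLM", lambda: glrlm_features(quantized, tuple(config.directions))),
        ("NGTDM", lambda: ngtdm_features(quantized)),
        ("GLSZM", lambda: glszm_features(quantized)),
        ("LBP", lambda: lbp_features(image, mask)),
    ]
    for family, fn in stages:
        try:
            values.update(fn())
        except Exception as exc:  # surface which family failed
            raise FeatureExtractionError(f"{family}: {exc}") from exc

    ordered = {name: float(values[name]) for name in manifest.FEATURE_NAMES}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise FeatureExtractionError(f"non-finite features: {bad}")
    return ordered


def extract_cohort(
    pairs: Sequence[tuple[str, ImageVolume, SegmentationMask]],
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Extract features for a cohort; returns samples x 102 DataFrame
    indexed by sample id."""
    rows = {sid: extract_all(img, msk, config) for sid, img, msk in pairs}
    return pd.DataFrame.from_dict(rows, orient="index")[manifest.FEATURE_NAMES]
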