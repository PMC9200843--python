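import numpy as np
import pytest

from radiophen.features.preprocess import ImageVolume, SegmentationMask, quantize
from radiophen.synthetic import (
    BatchDef,
    ClusterDef,
    CovariateDef,
    SurvivalDef,
    SyntheticSpec,
    simulate_feature_cohort,
    simulate_tumor_volume,
)


def random_quantized_grid(rng, max_shape=(4, 4, 3), max_levels=4, p_mask=0.8):
    """Small random quantized grid (levels 0..max_levels, 0 = out of mask)."""
    shape = tuple(int(rng.integers(2, s + 1)) for s in max_shape)
    lv = rng.integers(1, max_levels + 1, size=shape)
    lv[rng.random(shape) > p_mask] = 0
    if (lv > 0).sum() == 0:
        lv[0, 0, 0] = 1
    return lv


@pytest.fixture(scope="session")
def tumor_pair():
    return simulate_tumor_volume(radii=(7, 6, 5), texture="smooth",
                                 grid_shape=(24, 24, 24), seed=42)


@pytest.fixture(scope="session")
def small_roi():
    """5x5x5 random ROI with an ellipsoid-ish mask, quantized at 4 levels."""
    rng = np.random.default_rng(3)
    img = ImageVolume(rng.normal(0, 10, (5, 5, 5)))
    labels = np.ones((5, 5, 5), dtype=np.uint8)
    labels[0, 0, :] = 0
    mask = SegmentationMask(labels)
    return img, mask, quantize(img, mask, 4)


def single_batch_spec(n=500, n_features=50, gamma=1.5, delta=2.0, seed=0,
                      prop=(0.75, 0.25), feature_effect=0.0):
    """One batch variable with a planted location/scale effect on level B."""
    covs = []
    if feature_effect != 0.0:
        covs.append(CovariateDef("biomarker", "continuous",
                                 feature_effect=feature_effect))
    return SyntheticSpec(
        n_samples=n,
        n_features=n_features,
        batch_defs=[BatchDef("batch", ("A", "B"), prop,
                             (0.0, gamma), (1.0, delta))],
        cluster_def=ClusterDef(1, (1.0,), 0.0),
        covariate_defs=covs,
        survival_def=SurvivalDef(cluster_log_hr=(0.0,)),
        seed=seed,
    )


def two_batch_spec(n=200, n_features=50, gamma=1.5, delta=2.0, seed=0):
    """The standard two-batch-variable harmonization stress spec."""
    return SyntheticSpec(
        n_samples=n,
        n_features=n_features,
        batch_defs=[
            BatchDef("contrast", ("enh", "non"), (0.75, 0.25),
                     (0.0, gamma), (1.0, delta)),
            BatchDef("kernel", ("soft", "lung"), (0.85, 0.15),
                     (0.0, gamma), (1.0, delta)),
        ],
        cluster_def=ClusterDef(1, (1.0,), 0.0),
        survival_def=SurvivalDef(cluster_log_hr=(0.0,)),
        seed=seed,
    )


def clustered_spec(n=100, n_features=10, separation=6.0, k=2, seed=0):
    """Clean planted-cluster cohort (no batch effects, no covariates)."""
    return SyntheticSpec(
        n_samples=n,
        n_features=n_features,
        batch_defs=[],
        cluster_def=ClusterDef(k, tuple([1.0 / k] * k), separation),
        survival_def=SurvivalDef(cluster_log_hr=tuple([0.0] * k)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_cohort():
    """n=500 cohort with a single planted batch effect (gamma 1.5, delta 2)."""
    return simulate_feature_cohort(single_batch_spec(seed=0))


@pytest.fixture(scope="session")
def two_batch_cohort():
    """n=200, 50 features, two planted batch effects."""
    return simulate_feature_cohort(two_batch_spec(seed=1))
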