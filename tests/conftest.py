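import numpy as np
import pytest

from asymvbm.cohort import CohortConfig, EffectSpec, simulate_cohort
from asymvbm.volume import GMVolume, centered_affine


@pytest.fixture
def tiny_config():
    """Small even grid, quiet generator: good for exact-value checks."""
    return CohortConfig(
        n_asd=6,
        n_td=6,
        n_sites=2,
        grid_shape=(12, 14, 12),
        voxel_size=3.0,
        seed=7,
        noise_sd=0.0,
        site_bias_sd=0.0,
        age_volume_coef=0.0,
    )


@pytest.fixture
def small_config():
    """Small grid with default noise, for statistical checks."""
    return CohortConfig(
        n_asd=12, n_td=12, n_sites=3, grid_shape=(16, 18, 16), voxel_size=3.0, seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    """Centered random GM-probability volume on an even grid."""
    shape = (10, 12, 10)
    return GMVolume(rng.random(shape), centered_affine(shape, 3.0))


@pytest.fixture
def null_cohort(small_config):
    return simulate_cohort(small_config, [])


@pytest.fixture
def effect_cohort(small_config):
    eff = EffectSpec(
        region_center=(12.0, 0.0, 0.0),
        region_radius=9.0,
        delta=0.2,
        side="right",
        target="general_ASD",
    )
    return simulate_cohort(small_config, [eff]), eff
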