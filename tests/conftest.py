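import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mp2vbm.phantom import PhantomConfig, make_atlas, make_cohort, make_tissue_maps

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SMALL_GRID = (32, 36, 32)


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas(SMALL_GRID, voxel_size=2.0)


@pytest.fixture(scope="session")
def small_tissues(small_atlas):
    """One subject's tissue maps + dura mask on the small grid."""
    return make_tissue_maps(small_atlas, dura_thickness=1, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A minimal but complete cohort for fast integration tests."""
    cfg = PhantomConfig(grid_shape=SMALL_GRID, n_controls=4, n_patients=2,
                        lesion_radius=8.0, seed=11)
    subjects, atlas = make_cohort(cfg)
    return cfg, subjects, atlas


@pytest.fixture
def rng():
    return np.random.default_rng(42)
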