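import numpy as np
import pytest
from hypothesis import settings

from anxmvpa.synthetic_data import CohortSpec, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Desk-scale cohort: 6+6 subjects, 4 regions x 12 voxels, planted region 2."""
    return CohortSpec(
        n_anxious=6,
        n_control=6,
        atlas_shape=(6, 6, 6),
        n_regions=4,
        voxels_per_region=12,
        signal_region_id=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_ds(tiny_cohort):
    return tiny_cohort.to_dataset()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
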