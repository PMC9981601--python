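import numpy as np
import pytest

from ligload import synthgen


@pytest.fixture(scope="session")
def small_config():
    """A small but non-degenerate cohort configuration for fast tests."""
    return synthgen.SynthCohortConfig(
        n_subjects=8,
        volume_shape=(16, 16, 24),
        voxel_size=(0.7, 0.7, 1.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthgen.generate_porcine_cohort(small_config, seed=0)


@pytest.fixture(scope="session")
def surgical_map(small_config):
    return synthgen.generate_t2star_phantom(small_config, "surgical", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
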