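import numpy as np
import pytest

from latentrad.synthetic import LabelModel, PhantomConfig, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_config():
    """Desk-scale phantom grid used across tests."""
    return PhantomConfig(grid_shape=(24,) * 3, spacing_mm=(2.5,) * 3,
                         lesion_volume_range_ml=(4.0, 25.0), irregularity=0.15,
                         background_noise_sd=2.0, rim_noise_sd_range=(0.5, 3.0))


@pytest.fixture(scope="session")
def small_cohort(small_phantom_config):
    return generate_cohort(small_phantom_config, 12, LabelModel(), seed=123)


@pytest.fixture(scope="session")
def one_case(small_phantom_config):
    return generate_phantom(small_phantom_config, seed=99)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
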