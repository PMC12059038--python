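import numpy as np
import pytest

from slicemil.preprocess import WindowSpec, preprocess_record
from slicemil.synthetic import PhantomConfig, generate_cohort

TINY_SHAPE = (12, 24, 24)


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Small cohort used across tests: 20 exams of 12x24x24 voxels."""
    return PhantomConfig(
        n_exams=20,
        prevalence=0.3,
        central_fraction=0.5,
        volume_shape=TINY_SHAPE,
        central_lesion_radius=3,
        peripheral_lesion_radius=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_processed(tiny_cohort):
    return [
        preprocess_record(r, WindowSpec(), (12, 16, 16)) for r in tiny_cohort
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
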