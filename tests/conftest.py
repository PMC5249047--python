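import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")

from beadtask import PopulationConfig, TaskConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Twelve default agents through the default task; shared read-only."""
    return generate_dataset(PopulationConfig(n_subjects=12), TaskConfig(), seed=99)


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()
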