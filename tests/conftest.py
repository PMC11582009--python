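import numpy as np
import pytest
from hypothesis import settings

from mwfnet.pipeline import ExperimentConfig, project_dataset
from mwfnet.synthetic import PRESETS, make_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """12 synthetic neurons, 3 separable classes."""
    return make_dataset(PRESETS["separable-3"], per_class=4, seed=1)


@pytest.fixture(scope="session")
def fast_config():
    """Desk-scale config: 4 views, 48 px, short training."""
    return ExperimentConfig(
        phi_deg=90.0, image_size=48, epochs=6, batch_size=6, folds=3, seed=0,
        backbone_kwargs={"channels": (4, 8)},
    )


@pytest.fixture(scope="session")
def small_views(small_dataset, fast_config):
    return project_dataset(small_dataset.morphologies, fast_config.projection())
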