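import numpy as np
import pytest

import transtage as tt
from transtage.deepnet import TrainingConfig


@pytest.fixture(scope="session")
def small_spec():
    return tt.CohortSpec(n_samples=160, n_genes=300, module_sizes=(40, 25, 20),
                         module_directions=(-1, 1, 1), effect_size=1.5,
                         noise_sd=1.0, terminal_mass=0.4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return tt.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    """A quickly trained staging fit shared by trajectory/model tests."""
    cfg = TrainingConfig(epochs_init=80, epochs_joint=160, n_hidden=32,
                         seed=3, learning_rate=1e-3)
    model = tt.StagingModel.from_cohort(small_cohort, net_config=cfg,
                                        split_seed=3)
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
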