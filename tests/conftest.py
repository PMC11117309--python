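import numpy as np
import pytest

from helixsde import (
    SyntheticHelixConfig,
    VESDEParams,
    sample_maps,
    train,
)
from helixsde.nn import ScoreNet

# study conditions shared by the distribution-level tests: a 2,000-helix
# synthetic training set and one score model trained on it
TRAIN_SEED = 11
N_TRAIN = 2000


@pytest.fixture(scope="session")
def vesde() -> VESDEParams:
    return VESDEParams()


@pytest.fixture(scope="session")
def training_maps():
    return sample_maps(SyntheticHelixConfig(n_samples=N_TRAIN, seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def trained_model(training_maps, vesde):
    net = ScoreNet(seed=5)
    model, trace = train(
        net, training_maps, vesde, epochs=100, batch_size=128, seed=7, lr=2e-3
    )
    assert np.isfinite(trace[-1])
    model.loss_trace = trace  # kept for the training-dynamics checks
    return model
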