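import numpy as np
import pytest

from cocktail_ctx.embedding_context import SyntheticEmbeddingModel
from cocktail_ctx.synthetic_data import (
    ExperimentConfig,
    GroundTruth,
    generate_experiment,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One experiment generated under the default configuration."""
    return generate_experiment(ExperimentConfig(rng_seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick three-trial experiment for expensive downstream stages."""
    cfg = ExperimentConfig(
        n_trials=3, trial_duration_mean_s=20.0, words_per_trial_mean=60.0,
        words_per_trial_sd=3.0, rng_seed=11,
    )
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def adapter():
    return SyntheticEmbeddingModel.create(vocab_size=2000, dim=32, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_truth(n_electrodes=8, dim=32, seed=3, **kwargs):
    return GroundTruth.default(n_electrodes=n_electrodes, dim=dim, seed=seed, **kwargs)
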