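import numpy as np
import pytest

from rbpadda.adda_training import Mode, TrainingConfig, pretrain_source
from rbpadda.model_core import init_bundle
from rbpadda.seq_encoding import normalize_dataset, scale_dataset
from rbpadda.synthetic_data import SimulationConfig, generate_domain_pair


def small_sim(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down scenario for fast unit tests."""
    defaults = dict(n_source=300, n_target=150, seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_pair():
    """One small source/target pair, length-normalized and label-scaled."""
    source, target, truth = generate_domain_pair(small_sim(0))
    return (
        scale_dataset(normalize_dataset(source)),
        scale_dataset(normalize_dataset(target)),
        truth,
    )


@pytest.fixture(scope="session")
def trained_toy(small_pair):
    """A source network pre-trained briefly on the small scenario; enough
    signal for attribution tests without long training."""
    source, target, _ = small_pair
    cfg = TrainingConfig(n1=150, batch_size=64, seed=0)
    bundle, _ = pretrain_source(init_bundle(0), source, cfg)
    return bundle, source, target


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
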