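import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from semfuse.config import RunConfig
from semfuse.phantom import PhantomSpec, generate_pair


MICRO_CHANNELS = (2, 4, 4, 4, 4)


def micro_config(seed: int = 0) -> RunConfig:
    """Smallest config that still exercises 3 branches and 5 scales."""
    cfg = RunConfig()
    cfg.extract.channels = list(MICRO_CHANNELS)
    cfg.semantic.K = 3
    cfg.semantic.feature_dim = 8
    cfg.semantic.hidden = 4
    cfg.training.seed = seed
    cfg.training.batch_size = 2
    cfg.training.learning_rate = 1e-3
    cfg.training.cycles = 1
    cfg.training.fusion_epochs_per_cycle = 1
    cfg.training.seg_epochs_per_cycle = 1
    return cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pair_64():
    return generate_pair(PhantomSpec(height=64, width=64, seed=7))


@pytest.fixture(scope="session")
def phantom_pair_32():
    return generate_pair(PhantomSpec(height=32, width=32, seed=7,
                                     n_foci_a=1, n_masses_b=1))


@pytest.fixture(scope="session")
def micro_model():
    from semfuse.attention import FusionModel

    return FusionModel(channels=MICRO_CHANNELS, seed=3)
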