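import dataclasses

import numpy as np
import pytest

from arousalstack.config import RunConfig, SynthConfig
from arousalstack.pipeline import prepare_synthetic_features
from arousalstack.spectral import compute_dpss


@pytest.fixture(scope="session")
def tapers():
    return compute_dpss()


@pytest.fixture(scope="session")
def small_features():
    """A small but class-balanced synthetic feature set (6 records, 10 min)."""
    cfg = RunConfig(seed=11)
    return prepare_synthetic_features(cfg, n_records=6, record_duration=600.0)


@pytest.fixture(scope="session")
def default_synth_config():
    return SynthConfig(seed=5, record_duration=600.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_synth(seconds: float = 600.0, seed: int = 5, **overrides) -> SynthConfig:
    return dataclasses.replace(
        SynthConfig(seed=seed, record_duration=seconds), **overrides
    )
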