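import numpy as np
import pytest

from pullbacknet.models import ModelSpec
from pullbacknet.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def separable_cfg() -> SyntheticConfig:
    """Noise-free, transition-free conditions: classes are cleanly separable."""
    return SyntheticConfig(transition_width=0, noise_sd=0.0, noninformative_rate=0.0)


@pytest.fixture(scope="session")
def separable_cohort(separable_cfg):
    return generate_cohort(separable_cfg, 8, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """Small cohort under the default (noisy, blended) conditions."""
    return generate_cohort(SyntheticConfig(), 6, seed=21)


@pytest.fixture
def small_spec() -> ModelSpec:
    """Narrow model for fast unit tests."""
    return ModelSpec(head_kind="fc", widths=(4, 8, 8, 16), hidden_size=16)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
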