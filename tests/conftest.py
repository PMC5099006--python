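import numpy as np
import pytest

from firesync import SyntheticConfig, event_rule_fixture, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic realisation shared across tests."""
    return simulate_dataset(SyntheticConfig(), seed=3)


@pytest.fixture(scope="session")
def rule_fixture():
    """13 multi-tree + 3 cohort-verified single-scar fire years."""
    return event_rule_fixture(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
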