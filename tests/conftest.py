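import numpy as np
import pytest
from hypothesis import settings

from cugkit.synthetic_data import synthetic_usage_table

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def usage_table():
    """One session-wide synthetic usage table for recoding tests."""
    return synthetic_usage_table(2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
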