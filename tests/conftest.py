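import random

import pytest

from crcsim import Scenario, StrategyConfig


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def tiny_scenario():
    """A 2,000-person base-case scenario for fast end-to-end runs."""
    return Scenario().scaled(2000)


@pytest.fixture
def status_quo():
    return StrategyConfig.status_quo()


@pytest.fixture
def return_to_fit():
    return StrategyConfig.return_to_fit()
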