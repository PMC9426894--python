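import logging

import numpy as np
import pytest

import elgame as eg

# silence expected disconnected-graph warnings in test output
logging.getLogger("elgame.networks").setLevel(logging.ERROR)
logging.getLogger("elgame.dynamics").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pair_payoff_oracle(L1: eg.Language, L2: eg.Language) -> float:
    """Naive termwise double sum of the communication payoff."""
    total = 0.0
    for i in range(L1.n):
        for j in range(L1.m):
            total += L1.P[i, j] * L2.Q[j, i] + L2.P[i, j] * L1.Q[j, i]
    return 0.5 * total


@pytest.fixture
def pair_oracle():
    return pair_payoff_oracle
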