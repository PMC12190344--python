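import numpy as np
import pytest

from primosim.abm import ABMParams, AgentBreed, SpringParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_params():
    """ABM parameters with all stochastic processes disabled."""
    still = SpringParams(turnover_rate=0.0)
    return ABMParams().with_overrides(
        springs_by_breed={
            AgentBreed.WNTER: still,
            AgentBreed.FGFER: still,
            AgentBreed.DEPOSITER: SpringParams(turnover_rate=0.0, break_threshold=0.8),
        },
    )
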