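import numpy as np
import pytest

from prls_evosim import EcologicalParams, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def benign_ecology():
    """A forgiving environment for small pipeline tests: cheap survival
    (sigma2 = 2, steep slope), easy production, slow degradation — so tiny
    populations persist and generations turn over quickly."""
    return EcologicalParams(alpha=0.5, beta=0.5, gamma1=0.1, gamma2=10.0,
                            delta=0.1, sigma1=1.0, sigma2=2.0,
                            resource_pool=2000.0)


@pytest.fixture
def small_config(benign_ecology):
    return SimConfig(ecological=benign_ecology, initial_population=40,
                     duration=200, seed=7)
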