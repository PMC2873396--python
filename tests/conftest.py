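import numpy as np
import pytest

from amplidose.config import AnalysisThresholds, SimulationConfig


@pytest.fixture
def thresholds():
    return AnalysisThresholds()


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def exact_binomial_interval(n: int, p: float, conf: float = 0.99):
    """Exact central binomial interval for the observed count."""
    from scipy.stats import binom
    lo = binom.ppf((1 - conf) / 2, n, p)
    hi = binom.ppf(1 - (1 - conf) / 2, n, p)
    return int(lo), int(hi)
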