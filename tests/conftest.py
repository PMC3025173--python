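import numpy as np
import pytest

from famlik.params import FACTOR_NAMES, RiskParameters
from famlik.simulate import scenario_table


@pytest.fixture(scope="session")
def scenarios():
    return scenario_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_risk_parameters(rng, sd=0.5, alpha=None, names=FACTOR_NAMES):
    factors = {n: float(np.exp(rng.normal(0.0, sd))) for n in names}
    return RiskParameters(baseline_alpha=alpha, **factors)
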