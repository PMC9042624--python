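import numpy as np
import pytest

from plsfpm import DistributionSpec, SimulationConfig, simulate_survival

# one proper reference point per family, used across the suite
REFERENCE_SPECS = {
    "exponential": DistributionSpec("exponential", {"lam": 1.5}),
    "gompertz": DistributionSpec("gompertz", {"eta": 0.1, "b": 0.1}),
    "gengamma": DistributionSpec("gengamma", {"mu": 1.0, "sigma": 0.7, "kappa": 0.5}),
    "genf": DistributionSpec("genf", {"mu": 1.0, "sigma": 0.8, "s1": 2.0, "s2": 3.0}),
}


@pytest.fixture(params=list(REFERENCE_SPECS))
def family_spec(request):
    return REFERENCE_SPECS[request.param]


@pytest.fixture(scope="session")
def default_dataset():
    """The default simulation design: Gompertz(0.1, 0.1), n=100, p=30."""
    return simulate_survival(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
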