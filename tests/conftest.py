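import pytest

from coalafs import build_demography


@pytest.fixture
def constant_1000():
    return build_demography("constant", N0=1000)


@pytest.fixture
def exponential_growth():
    """Exponential growth, N0 = 100,000 and gamma = 0.003 per generation."""
    return build_demography("exponential", N0=1e5, gamma=0.003)


@pytest.fixture
def logistic_model():
    """Logistic growth to Nk = 10,000 over T = 5000 generations."""
    return build_demography("logistic", Nk=10000, gamma=0.003, T=5000)


@pytest.fixture
def gompertz_model():
    """Gompertz growth from a single founder over T = 5000 generations."""
    return build_demography("gompertz", N0=1, gamma=0.01, alpha=0.001, T=5000)


@pytest.fixture
def three_epoch():
    """Bottleneck history: 10k now, 500 from 100 to 1100 gens ago, 5k older."""
    return build_demography("piecewise",
                            times=[0.0, 100.0, 1100.0],
                            sizes=[10000.0, 500.0, 5000.0])
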