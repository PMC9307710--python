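import numpy as np
import pytest

from seqsdt import LineupDesign, ParameterSet, builtin_table


@pytest.fixture(scope="session")
def wilson():
    return builtin_table("wilson")


@pytest.fixture(scope="session")
def dunn():
    return builtin_table("dunn")


@pytest.fixture
def binary_design():
    return LineupDesign(6, 1)


@pytest.fixture
def confidence_design():
    return LineupDesign(6, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_parameters(rng, I=6, K=None, mixture=False):
    """A random admissible ParameterSet for property tests."""
    kw = {}
    if K is not None and K > 1:
        kw.update(kappa=rng.uniform(0.05, 0.6, (I, K - 1)),
                  omega=float(np.exp(rng.normal(0, 0.3))),
                  eta=float(rng.normal(0, 0.3)),
                  gamma=float(rng.normal(0, 0.3)))
    if mixture:
        kw.update(pi_serious=float(rng.uniform(0.7, 1.0)),
                  zeta=float(np.exp(rng.normal(0, 0.4))))
    return ParameterSet(
        mu_T=float(rng.normal(0.8, 0.4)),
        sigma2_T=float(np.exp(rng.normal(0, 0.4))),
        tau0=rng.normal(0.1, 0.4, I),
        delta=float(rng.normal(0, 0.8)),
        lambda_=float(np.abs(rng.normal(0, 0.5))),
        **kw,
    )
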