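import numpy as np
import pytest

from dagumcens import DagumParams, InspectionScheme, quantile, simulate

TRUE = DagumParams(2.0, 2.0, 1.0)
DEFAULT_PROBS = np.array([0.15, 0.35, 0.55, 0.75, 0.95])


@pytest.fixture(scope="session")
def true_params():
    return TRUE


def make_scheme(params=TRUE, props=(0.0, 0.0, 0.0, 0.0, 1.0), probs=DEFAULT_PROBS):
    """Inspection grid at true-law quantiles with the given removal scheme."""
    return InspectionScheme(quantile(np.asarray(probs), params), props)


@pytest.fixture(scope="session")
def scheme_plain():
    """Conventional interval censoring: no intermediate removals."""
    return make_scheme()


@pytest.fixture(scope="session")
def scheme_progressive():
    """Progressive removals p = (0, 0.2, 0.5, 0.75, 1)."""
    return make_scheme(props=(0.0, 0.2, 0.5, 0.75, 1.0))


@pytest.fixture(scope="session")
def dataset_medium(scheme_progressive):
    return simulate(TRUE, 500, scheme_progressive, seed=11)


@pytest.fixture(scope="session")
def dataset_large(scheme_plain):
    return simulate(TRUE, 2000, scheme_plain, seed=3)


def random_params(rng, low=-0.7, high=0.9):
    return DagumParams(*np.exp(rng.uniform(low, high, 3)))
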