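import numpy as np
import pytest

from ekdesign import CandidateSet, CovarianceKernel, Design, GPModel, maximin_lh


@pytest.fixture(scope="session")
def exp_kernel():
    return CovarianceKernel("exponential", {"nu": 7.0})


@pytest.fixture(scope="session")
def example_model(exp_kernel):
    """Constant trend, sigma2=1, exponential correlation with nu=7."""
    return GPModel(kernel=exp_kernel, sigma2=1.0, trend="constant")


@pytest.fixture(scope="session")
def grid25():
    return CandidateSet.grid(25)


@pytest.fixture(scope="session")
def grid4():
    """Tiny 4x4 grid (Q=16) for exhaustive checks."""
    return CandidateSet.grid(4)


@pytest.fixture(scope="session")
def lh7():
    """The 7-point maximin/minimax Latin hypercube initial design."""
    return maximin_lh(7)


@pytest.fixture(scope="session")
def exchange_front(example_model, grid25, lh7):
    from ekdesign import exchange_search

    return exchange_search(lh7, example_model, grid25, "front")


@pytest.fixture(scope="session")
def exchange_hull(example_model, grid25, lh7):
    from ekdesign import exchange_search

    return exchange_search(lh7, example_model, grid25, "hull")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_design(rng, n=5, d=2):
    pts = rng.random((n, d))
    return Design(pts)
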