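import numpy as np
import pandas as pd
import pytest

from jointprev import AdjacencyGraph, ParameterSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def path5():
    """Five-node path graph 0-1-2-3-4."""
    return AdjacencyGraph.from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])


@pytest.fixture
def single_node_graph():
    return AdjacencyGraph(1, [[]])


@pytest.fixture
def counties10(rng):
    """Ten counties in two states with assorted covariates."""
    return pd.DataFrame({
        "county": np.arange(1, 11),
        "state": [1] * 5 + [2] * 5,
        "poverty": rng.uniform(0.02, 0.4, 10),
        "log_density": rng.normal(4.0, 1.5, 10),
        "top_black": [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        "top_hisp": [0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
        "top_other": [0, 0, 0, 0, 0, 0, 0, 0, 1, 0],
    })


@pytest.fixture
def respondents20(rng):
    """Twenty respondents spread over the ten counties."""
    n = 20
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age_group": rng.integers(1, 13, n),
        "race": rng.integers(1, 5, n),
        "education": rng.integers(1, 5, n),
        "county": rng.integers(1, 11, n),
        "weight": rng.uniform(0.5, 4.0, n),
        "category": rng.integers(1, 7, n),
    })


def random_params(rng, n_counties=10, n_states=2, constrained=True):
    """A random but constraint-satisfying parameter set."""
    p = ParameterSet.zeros(n_counties, n_states)
    p.alpha = rng.normal(0, 1, 5)
    p.beta[:, 1:] = rng.normal(0, 0.5, (5, 3))
    p.gamma[:, 1:] = rng.normal(0, 0.5, (5, 3))
    p.eta = rng.normal(0, 0.3, (5, 12))
    p.delta = rng.normal(0, 0.3, (5, 5))
    p.v = rng.normal(0, 0.5, n_counties)
    p.u = rng.normal(0, 0.3, n_states)
    p.lam[1:] = rng.normal(1, 0.3, 4)
    p.kappa[1:] = rng.normal(1, 0.3, 4)
    p.sigma2_v = 0.3
    p.sigma2_u = 0.1
    if constrained:
        p.eta -= p.eta.mean(axis=1, keepdims=True)
        p.v -= p.v.mean()
        p.u -= p.u.mean()
    return p
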