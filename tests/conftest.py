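import numpy as np
import pytest

from dynsbm import DynSBMParams, DynamicNetwork, community_params, simulate


def random_tiny_instance(seed, n=4, t=2, q=2, m=1):
    """A small simulated network with generic (asymmetric-in-groups) params,
    suitable for exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    alpha = rng.dirichlet(np.full(q, 5.0))
    pi = rng.dirichlet(np.full(q, 5.0), size=q)
    b = rng.uniform(0.15, 0.85, size=(q, q, t))
    b = (b + b.transpose(1, 0, 2)) / 2
    b[np.arange(q), np.arange(q), :] = b[np.arange(q), np.arange(q), :1]
    gamma = None
    if m > 1:
        g = rng.dirichlet(np.full(m, 3.0), size=(q, q, t))
        g = (g + g.transpose(1, 0, 2, 3)) / 2
        g /= g.sum(axis=3, keepdims=True)
        g[np.arange(q), np.arange(q)] = g[np.arange(q), np.arange(q), :1]
        gamma = g
    params = DynSBMParams(alpha, pi, b, gamma)
    presence = np.ones((n, t), dtype=bool)
    net, Z = simulate(params, presence, seed=seed + 10_000)
    return net, Z, params


@pytest.fixture
def tiny():
    return random_tiny_instance(0)


@pytest.fixture
def planted_small():
    """Well-separated two-group network, small enough to enumerate."""
    params = community_params(q=2, n_steps=2, beta_within=0.8,
                              beta_between=0.1, pi_stay=0.9)
    net, Z = simulate(params, np.ones((5, 2), dtype=bool), seed=42)
    return net, Z, params


@pytest.fixture
def toy6():
    """Six nodes, two groups, three steps, hand-checkable memberships."""
    Z = np.array([
        [1, 1, 1],
        [1, 1, 2],
        [1, 2, 2],
        [2, 2, 2],
        [2, 2, 2],
        [2, 0, 2],   # absent in the middle
    ])
    return Z
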