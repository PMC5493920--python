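"""Generative dynamic stochastic block model: parameters and simulation.

Each node follows a hidden Markov chain over Q groups (initial law ``alpha``,
shared transition matrix ``pi``).  Conditionally on groups, each observable
dyad (i, j) at step t is drawn from a zero-inflated categorical emission:

    P(Y = 0)             = 1 - beta[q, l, t]
    P(Y = m), m = 1..M   = beta[q, l, t] * gamma[q, l, t, m - 1]

where q, l are the groups of i and j.  With M = 1 this reduces to a Bernoulli
edge model.  Within-group (diagonal) emission parameters are held constant in
time: time-varying memberships make group labels identifiable across steps
only if groups carry a time-stable signature, and intra-group connectivity is
that anchor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .netdata import DynamicNetwork

__all__ = [
    "DynSBMParams",
    "MembershipTrajectories",
    "simulate_memberships",
    "simulate_network",
    "simulate",
    "make_fixture",
    "community_params",
    "multinomial_recovery_params",
    "log_emission_table",
]

_STOCH_TOL = 1e-12


@dataclass
class DynSBMParams:
    """Full parameter set of a dynSBM.

    alpha : (Q,) initial group distribution
    pi : (Q, Q) Markov transition matrix (rows sum to 1)
    beta : (Q, Q, T) edge-presence probabilities
    gamma : (Q, Q, T, M) category distributions among present edges
            (None when M = 1)
    """

    alpha: np.ndarray
    pi: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray | None = None
    directed: bool = False
    self_loops: bool = False

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
        self.validate()

    @property
    def q_groups(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_steps(self) -> int:
        return self.beta.shape[2]

    @property
    def n_categories(self) -> int:
        return 1 if self.gamma is None else self.gamma.shape[3]

    def validate(self) -> None:
        Q = self.q_groups
        if abs(self.alpha.sum() - 1.0) > _STOCH_TOL or np.any(self.alpha < 0):
            raise ValueError("alpha must be a probability vector")
        if self.pi.shape != (Q, Q):
            raise ValueError("pi must be Q x Q")
        if np.any(self.pi < 0) or np.any(np.abs(self.pi.sum(axis=1) - 1.0) > _STOCH_TOL):
            raise ValueError("rows of pi must sum to 1")
        if self.beta.shape[:2] != (Q, Q) or self.beta.ndim != 3:
            raise ValueError("beta must be Q x Q x T")
        if np.any(self.beta < 0) or np.any(self.beta > 1):
            raise ValueError("beta entries must be in [0, 1]")
        diag = self.beta[np.arange(Q), np.arange(Q), :]
        if not np.allclose(diag, diag[:, :1], atol=1e-10):
            raise ValueError("diagonal beta[q, q, :] must be constant in time")
        if not self.directed and not np.allclose(
                self.beta, self.beta.transpose(1, 0, 2), atol=1e-10):
            raise ValueError("undirected model needs symmetric beta")
        if self.gamma is not None:
            if self.gamma.shape[:3] != self.beta.shape:
                raise ValueError("gamma must be Q x Q x T x M")
            if np.any(self.gamma < 0) or np.any(
                    np.abs(self.gamma.sum(axis=3) - 1.0) > 1e-10):
                raise ValueError("each gamma[q, l, t] must sum to 1")
            gdiag = self.gamma[np.arange(Q), np.arange(Q), :, :]
            if not np.allclose(gdiag, gdiag[:, :1, :], atol=1e-10):
                raise ValueError("diagonal gamma[q, q, :, :] must be constant in time")
            if not self.directed and not np.allclose(
                    self.gamma, self.gamma.transpose(1, 0, 2, 3), atol=1e-10):
                raise ValueError("undirected model needs symmetric gamma")

    def to_json(self, path: str | None = None) -> str:
        doc = {
            "alpha": self.alpha.tolist(),
            "pi": self.pi.tolist(),
            "beta": self.beta.tolist(),
            "gamma": None if self.gamma is None else self.gamma.tolist(),
            "directed": self.directed,
            "self_loops": self.self_loops,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "DynSBMParams":
        """Load from a JSON string or a path to a JSON file."""
        if source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        gamma = None if doc.get("gamma") is None else np.array(doc["gamma"])
        return cls(np.array(doc["alpha"]), np.array(doc["pi"]),
                   np.array(doc["beta"]), gamma,
                   directed=bool(doc.get("directed", False)),
                   self_loops=bool(doc.get("self_loops", False)))


@dataclass
class MembershipTrajectories:
    """Group trajectories Z (N x T ints in {0..Q}); 0 marks absent node-steps."""

    Z: np.ndarray
    q_groups: int = field(default=0)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.int64)
        if self.q_groups == 0:
            self.q_groups = int(self.Z.max(initial=1))
        if self.Z.min(initial=0) < 0 or self.Z.max(initial=0) > self.q_groups:
            raise ValueError("memberships must lie in {0, ..., Q}")

    @property
    def presence(self) -> np.ndarray:
        return self.Z > 0


def log_emission_table(params: DynSBMParams) -> np.ndarray:
    """log f(y; Theta[q, l, t]) as a (T, Q, Q, M+1) array (true -inf at 0)."""
    Q, T, M = params.q_groups, params.n_steps, params.n_categories
    beta = params.beta.transpose(2, 0, 1)  # (T, Q, Q)
    out = np.empty((T, Q, Q, M + 1))
    with np.errstate(divide="ignore"):
        out[..., 0] = np.log(1.0 - beta)
        if M == 1:
            out[..., 1] = np.log(beta)
        else:
            gamma = params.gamma.transpose(2, 0, 1, 3)  # (T, Q, Q, M)
            out[..., 1:] = np.log(beta)[..., None] + np.log(gamma)
    return out


def simulate_memberships(params: DynSBMParams, presence: np.ndarray,
                         seed: int) -> MembershipTrajectories:
    """Draw one Markov group chain per node along its present steps.

    The group at a node's first present step follows ``alpha``; between two
    consecutive present steps one application of ``pi`` bridges the gap,
    however long the absence in between.  Absent steps get group 0.
    """
    presence = np.asarray(presence, dtype=bool)
    if np.any(presence.sum(axis=1) == 0):
        raise ValueError("every node needs at least one present step")
    rng = np.random.default_rng(seed)
    N, T = presence.shape
    Q = params.q_groups
    Z = np.zeros((N, T), dtype=np.int64)
    for i in range(N):
        steps = np.flatnonzero(presence[i])
        g = rng.choice(Q, p=params.alpha)
        Z[i, steps[0]] = g + 1
        for t in steps[1:]:
            g = rng.choice(Q, p=params.pi[g])
            Z[i, t] = g + 1
    return MembershipTrajectories(Z, q_groups=Q)


def simulate_network(params: DynSBMParams, Z: MembershipTrajectories,
                     seed: int) -> DynamicNetwork:
    """Draw snapshots given memberships, from the zero-inflated emissions."""
    rng = np.random.default_rng(seed)
    Zm = Z.Z
    N, T = Zm.shape
    if T != params.n_steps:
        raise ValueError("memberships and params disagree on T")
    M = params.n_categories
    values = np.zeros((T, N, N), dtype=np.int64)
    for t in range(T):
        present = np.flatnonzero(Zm[:, t] > 0)
        n = present.size
        if n == 0:
            continue
        g = Zm[present, t] - 1
        bmat = params.beta[np.ix_(g, g)][:, :, t]
        edge = rng.random((n, n)) < bmat
        if M == 1:
            y = edge.astype(np.int64)
        else:
            gmat = params.gamma[np.ix_(g, g)][:, :, t, :]      # (n, n, M)
            cum = np.cumsum(gmat, axis=2)
            u = rng.random((n, n))
            y = np.where(edge, 1 + (u[:, :, None] >= cum).sum(axis=2), 0)
            y = np.minimum(y, M)  # guard cumulative rounding at 1.0
        loops = np.diagonal(y).copy()
        if params.directed:
            np.fill_diagonal(y, 0)
        else:
            y = np.triu(y, k=1)
            y = y + y.T
        if params.self_loops:
            y[np.arange(n), np.arange(n)] = loops
        values[t][np.ix_(present, present)] = y
    return DynamicNetwork(values, Z.presence, params.directed,
                          params.self_loops, M)


def simulate(params: DynSBMParams, presence: np.ndarray, seed: int
             ) -> tuple[DynamicNetwork, MembershipTrajectories]:
    """Memberships then network, both driven by one seed."""
    ss = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
    Z = simulate_memberships(params, presence, int(ss[0]))
    net = simulate_network(params, Z, int(ss[1]))
    return net, Z


def _sticky_pi(q: int, stay: float) -> np.ndarray:
    pi = np.full((q, q), (1.0 - stay) / (q - 1)) if q > 1 else np.ones((1, 1))
    if q > 1:
        np.fill_diagonal(pi, stay)
    return pi


def community_params(q: int = 3, n_steps: int = 10, beta_within: float = 0.4,
                     beta_between: float = 0.05, pi_stay: float = 0.9,
                     directed: bool = False, self_loops: bool = False
                     ) -> DynSBMParams:
    """Planted-community Bernoulli parameters: dense within-group blocks on a
    sparse background, sticky membership chains."""
    beta = np.full((q, q, n_steps), beta_between)
    for g in range(q):
        beta[g, g, :] = beta_within
    return DynSBMParams(np.full(q, 1.0 / q), _sticky_pi(q, pi_stay), beta,
                        None, directed=directed, self_loops=self_loops)


def multinomial_recovery_params(n_steps: int = 5) -> DynSBMParams:
    """Three-group weighted model with a distinct intensity profile per block
    pair, for checking recovery of the category distributions gamma."""
    q, m = 3, 3
    beta = np.full((q, q, n_steps), 0.6)
    for g in range(q):
        beta[g, g, :] = 0.9
    profiles = {
        (0, 0): [0.55, 0.30, 0.15],
        (1, 1): [0.15, 0.25, 0.60],
        (2, 2): [0.30, 0.50, 0.20],
        (0, 1): [0.30, 0.40, 0.30],
        (0, 2): [0.50, 0.30, 0.20],
        (1, 2): [0.70, 0.20, 0.10],
    }
    gamma = np.zeros((q, q, n_steps, m))
    for (a, b), p in profiles.items():
        gamma[a, b, :, :] = p
        gamma[b, a, :, :] = p
    return DynSBMParams(np.full(q, 1.0 / q), _sticky_pi(q, 0.9), beta, gamma)


def _ants_like_params() -> DynSBMParams:
    """Undirected weighted model at the scale of a tracked ant colony:
    three groups, strong intra-group contact, one pair of groups nearly
    disconnected and interacting only at low intensity."""
    q, T, m = 3, 10, 3
    base = np.array([[0.85, 0.50, 0.45],
                     [0.50, 0.90, 0.08],
                     [0.45, 0.08, 0.75]])
    beta = np.repeat(base[:, :, None], T, axis=2)
    # mild seasonal wobble on off-diagonal connectivity (diagonal stays flat)
    wobble = 0.04 * np.sin(2 * np.pi * np.arange(T) / T)
    for a in range(q):
        for b in range(q):
            if a != b:
                beta[a, b, :] = np.clip(base[a, b] + wobble, 0.01, 0.99)
    profiles = {
        (0, 0): [0.50, 0.30, 0.20],
        (1, 1): [0.15, 0.25, 0.60],
        (2, 2): [0.40, 0.35, 0.25],
        (0, 1): [0.30, 0.40, 0.30],
        (0, 2): [0.45, 0.35, 0.20],
        (1, 2): [0.70, 0.20, 0.10],
    }
    gamma = np.zeros((q, q, T, m))
    for (a, b), p in profiles.items():
        gamma[a, b, :, :] = p
        gamma[b, a, :, :] = p
    return DynSBMParams(np.full(q, 1.0 / q), _sticky_pi(q, 0.9), beta, gamma)


def _foodweb_like_params() -> DynSBMParams:
    """Directed binary model with self-loops at the scale of a small seasonal
    food web: top predators (group 4) eat everything and are eaten only
    within their own group (cannibalism), intermediate predators (group 3)
    eat the prey groups, peripheral species (group 1) barely interact."""
    q, T = 4, 6
    base = np.array([
        #  eats: periph  prey   interm  top
        [0.05, 0.05, 0.05, 0.05],   # peripheral
        [0.05, 0.05, 0.05, 0.05],   # common prey
        [0.60, 0.75, 0.30, 0.05],   # intermediate predators
        [0.70, 0.85, 0.70, 0.60],   # top predators
    ])
    beta = np.repeat(base[:, :, None], T, axis=2)
    return DynSBMParams(np.full(q, 1.0 / q), _sticky_pi(q, 0.85), beta, None,
                        directed=True, self_loops=True)


_SCENARIOS = {"ants_like", "foodweb_like"}


def make_fixture(scenario: str, seed: int
                 ) -> tuple[DynamicNetwork, MembershipTrajectories, DynSBMParams]:
    """Simulate a documented test scenario.

    ``"ants_like"``: N=152, T=10, Q=3, M=3, undirected, everyone present.
    ``"foodweb_like"``: N=26, T=6, Q=4, binary, directed with self-loops,
    roughly 20% of node-steps absent.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIOS)}")
    if scenario == "ants_like":
        params = _ants_like_params()
        presence = np.ones((152, params.n_steps), dtype=bool)
    else:
        params = _foodweb_like_params()
        rng = np.random.default_rng(np.random.SeedSequence([seed, 815]).generate_state(1)[0] % (2 ** 31))
        presence = rng.random((26, params.n_steps)) > 0.2
        # every node must be present somewhere
        for i in np.flatnonzero(presence.sum(axis=1) == 0):
            presence[i, rng.integers(params.n_steps)] = True
    net, Z = simulate(params, presence, seed)
    return net, Z, params
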