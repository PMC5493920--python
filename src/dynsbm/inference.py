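"""Variational EM for the dynamic stochastic block model.

The posterior over the N coupled membership chains is intractable, so it is
approximated by a product over nodes of Markov chains on each node's present
steps: coupling *across* nodes is broken, temporal dependence *within* a node
is kept.  The E-step is a mean-field fixed point — each node's chain is
re-estimated exactly (forward–backward) given the current marginals of the
others — and the M-step maximizes the expected complete log-likelihood in
closed form.  The resulting evidence lower bound (ELBO) increases at every
step and never exceeds the exact log marginal likelihood, which
:func:`exact_log_marginal` computes by enumeration on tiny instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, xlogy

from .genmodel import DynSBMParams, MembershipTrajectories, log_emission_table
from .netdata import DynamicNetwork, write_memberships

__all__ = [
    "VariationalState",
    "FitResult",
    "complete_log_likelihood",
    "exact_log_marginal",
    "e_step",
    "m_step",
    "elbo",
    "fit",
]

EPS = 1e-6          # M-step smoothing; keeps every fitted probability positive
_LOG_FLOOR = -1e30  # stands in for log 0 inside messages


@dataclass
class VariationalState:
    """Per-node variational chains.

    tau : (N, T, Q) group marginals; rows are zero at absent node-steps
    xi : per node, a (K_i - 1, Q, Q) array of joint posteriors over the
         node's consecutive present-step pairs (K_i = number of present steps)
    """

    tau: np.ndarray
    xi: list[np.ndarray]

    @property
    def q_groups(self) -> int:
        return self.tau.shape[2]

    def copy(self) -> "VariationalState":
        return VariationalState(self.tau.copy(), [x.copy() for x in self.xi])

    def validate(self, presence: np.ndarray, atol: float = 1e-8) -> None:
        present = np.asarray(presence, dtype=bool)
        sums = self.tau.sum(axis=2)
        if present.any() and not np.allclose(sums[present], 1.0, atol=1e-10):
            raise ValueError("tau rows at present node-steps must sum to 1")
        if np.any(np.abs(sums[~present]) > 1e-12):
            raise ValueError("tau rows at absent node-steps must be zero")
        for i, x in enumerate(self.xi):
            steps = np.flatnonzero(present[i])
            if x.shape[0] != max(len(steps) - 1, 0):
                raise ValueError("xi length inconsistent with presence")
            for k in range(x.shape[0]):
                if abs(x[k].sum() - 1.0) > atol:
                    raise ValueError("each xi matrix must sum to 1")
                if not np.allclose(x[k].sum(axis=1), self.tau[i, steps[k]], atol=atol):
                    raise ValueError("xi row sums must match the left tau marginal")
                if not np.allclose(x[k].sum(axis=0), self.tau[i, steps[k + 1]], atol=atol):
                    raise ValueError("xi column sums must match the right tau marginal")


@dataclass
class FitResult:
    params: DynSBMParams
    state: VariationalState
    map_memberships: MembershipTrajectories
    elbo_trace: list[float]
    converged: bool
    n_iterations: int
    seed_used: int
    icl: float | None = field(default=None)
    all_traces: list[list[float]] = field(default_factory=list)

    @property
    def elbo(self) -> float:
        return self.elbo_trace[-1]

    def write_memberships(self, path: str,
                          node_labels: list[str] | None = None) -> None:
        write_memberships(self.map_memberships.Z, path, node_labels)

    def to_json(self, path: str | None = None) -> str:
        import json
        doc = {
            "params": json.loads(self.params.to_json()),
            "elbo_trace": [float(v) for v in self.elbo_trace],
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "seed": self.seed_used,
            "icl": self.icl,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# shared pieces

def _as_Z(Z) -> np.ndarray:
    return Z.Z if isinstance(Z, MembershipTrajectories) else np.asarray(Z, dtype=np.int64)

def _present_steps(presence: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(presence[i]) for i in range(presence.shape[0])]

def _one_hot_values(net: DynamicNetwork) -> np.ndarray:
    """(T, N, N, M+1) indicator array of edge categories."""
    M = net.n_categories
    eye = np.eye(M + 1)
    return eye[net.values]

def _safe_log(x: np.ndarray) -> np.ndarray:
    out = np.full_like(x, _LOG_FLOOR, dtype=float)
    np.log(x, out=out, where=x > 0)
    return out

def _block_counts(net: DynamicNetwork, tau: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Expected dyad-category counts per block.

    Returns (C, S): C[t, q, l, m] sums tau_itq * tau_jtl over dyads (one per
    unordered pair when undirected, ordered otherwise, i != j), S[t, q, m]
    sums tau_itq over self-loops.  Absent nodes have zero tau rows and drop
    out automatically.
    """
    T, N = net.n_steps, net.n_nodes
    Q = tau.shape[2]
    M = net.n_categories
    Yoh = _one_hot_values(net)
    C = np.empty((T, Q, Q, M + 1))
    S = np.zeros((T, Q, M + 1))
    diag_idx = np.arange(N)
    for t in range(T):
        tt = tau[:, t, :]
        A = np.einsum("ijm,jl->ilm", Yoh[t], tt)
        Ct = np.einsum("iq,ilm->qlm", tt, A)
        Ydiag = Yoh[t, diag_idx, diag_idx, :]
        Ct -= np.einsum("iq,il,im->qlm", tt, tt, Ydiag)
        C[t] = Ct
        S[t] = tt.T @ Ydiag
    if not net.directed:
        C = (C + C.transpose(0, 2, 1, 3)) / 2.0  # enforce exact symmetry
        C /= 2.0  # the ordered sum visited each unordered pair twice
    return C, S


def _node_messages(Yoh: np.ndarray, tau: np.ndarray, logf_safe: np.ndarray,
                   i: int, directed: bool, self_loops: bool,
                   values: np.ndarray) -> np.ndarray:
    """log rho for node i: (T, Q) sums of expected log-emissions against all
    other present nodes (both edge directions when directed)."""
    T, Q = logf_safe.shape[0], logf_safe.shape[1]
    c_out = np.einsum("tjm,jtl->tlm", Yoh[:, i, :, :], tau)
    c_out -= np.einsum("tm,tl->tlm", Yoh[:, i, i, :], tau[i])
    msg = np.einsum("tlm,tqlm->tq", c_out, logf_safe)
    if directed:
        c_in = np.einsum("tjm,jtl->tlm", Yoh[:, :, i, :], tau)
        c_in -= np.einsum("tm,tl->tlm", Yoh[:, i, i, :], tau[i])
        msg += np.einsum("tlm,tlqm->tq", c_in, logf_safe)
    if self_loops:
        qq = np.arange(Q)
        msg += logf_safe[np.arange(T)[:, None], qq[None, :], qq[None, :],
                         values[:, i, i][:, None]]
    return msg


def _lse(a: np.ndarray, axis: int | None = None):
    """Log-sum-exp on small dense arrays (scipy's wrapper is too heavy here)."""
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))
    return float(out.reshape(())) if axis is None else np.squeeze(out, axis=axis)


def _forward_backward(log_init: np.ndarray, log_trans: np.ndarray,
                      log_emit: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact chain posterior: marginals (K, Q) and pairwise joints (K-1, Q, Q)."""
    K, Q = log_emit.shape
    fwd = np.empty((K, Q))
    fwd[0] = log_init + log_emit[0]
    for k in range(1, K):
        fwd[k] = log_emit[k] + _lse(fwd[k - 1][:, None] + log_trans, axis=0)
    ll = _lse(fwd[-1])
    bwd = np.zeros((K, Q))
    for k in range(K - 2, -1, -1):
        bwd[k] = _lse(log_trans + (log_emit[k + 1] + bwd[k + 1])[None, :], axis=1)
    tau = np.exp(fwd + bwd - ll)
    tau /= tau.sum(axis=1, keepdims=True)
    xi = np.empty((K - 1, Q, Q))
    for k in range(K - 1):
        x = np.exp(fwd[k][:, None] + log_trans
                   + (log_emit[k + 1] + bwd[k + 1])[None, :] - ll)
        xi[k] = x / x.sum()
    return tau, xi


def _viterbi(log_init: np.ndarray, log_trans: np.ndarray,
             log_emit: np.ndarray) -> np.ndarray:
    """Most probable path; ties broken toward the lowest group index."""
    K, Q = log_emit.shape
    delta = log_init + log_emit[0]
    back = np.zeros((K, Q), dtype=np.int64)
    for k in range(1, K):
        scores = delta[:, None] + log_trans
        back[k] = np.argmax(scores, axis=0)
        delta = log_emit[k] + np.max(scores, axis=0)
    path = np.empty(K, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for k in range(K - 2, -1, -1):
        path[k] = back[k + 1][path[k + 1]]
    return path


# ---------------------------------------------------------------------------
# likelihood quantities

def complete_log_likelihood(net: DynamicNetwork, Z, params: DynSBMParams) -> float:
    """log P(Y, Z; params); -inf (not an exception) for zero-probability
    configurations such as a transition forbidden by pi."""
    Zm = _as_Z(Z)
    if Zm.shape != (net.n_nodes, net.n_steps):
        raise ValueError("Z has wrong shape")
    if not np.array_equal(Zm > 0, net.presence):
        raise ValueError("Z must be 0 exactly at absent node-steps")
    if Zm.max(initial=0) > params.q_groups:
        raise ValueError("Z has more groups than params")
    with np.errstate(divide="ignore"):
        log_alpha = np.log(params.alpha)
        log_pi = np.log(params.pi)
    logf = log_emission_table(params)

    total = 0.0
    for i in range(net.n_nodes):
        steps = np.flatnonzero(net.presence[i])
        if steps.size == 0:
            continue
        g = Zm[i, steps] - 1
        total += log_alpha[g[0]]
        if g.size > 1:
            total += log_pi[g[:-1], g[1:]].sum()
    for t in range(net.n_steps):
        p = np.flatnonzero(net.presence[:, t])
        if p.size == 0:
            continue
        g = Zm[p, t] - 1
        sub = net.values[t][np.ix_(p, p)]
        L = logf[t][g[:, None], g[None, :], sub]
        if net.directed:
            dyads = L[~np.eye(p.size, dtype=bool)].sum()
        else:
            dyads = L[np.triu_indices(p.size, k=1)].sum()
        total += dyads
        if net.self_loops:
            total += np.diagonal(L).sum()
    return float(total)


def exact_log_marginal(net: DynamicNetwork, params: DynSBMParams,
                       limit: int = 2 ** 20) -> float:
    """log P(Y; params) by exhaustive enumeration over all membership
    configurations (log-sum-exp stabilized).  Only for tiny instances."""
    Q = params.q_groups
    steps = _present_steps(net.presence)
    n_cells = int(net.presence.sum())
    if Q ** n_cells > limit:
        raise ValueError(f"instance too large to enumerate: Q^{n_cells} > {limit}")
    per_node = []
    for s in steps:
        per_node.append(list(itertools.product(range(1, Q + 1), repeat=len(s))))
    lls = []
    Zm = np.zeros((net.n_nodes, net.n_steps), dtype=np.int64)
    for combo in itertools.product(*per_node):
        for i, (s, traj) in enumerate(zip(steps, combo)):
            Zm[i, s] = traj
        lls.append(complete_log_likelihood(net, Zm, params))
    return float(logsumexp(np.array(lls)))


def elbo(net: DynamicNetwork, params: DynSBMParams,
         state: VariationalState) -> float:
    """Expected complete log-likelihood plus the entropy of the variational
    chains; a lower bound on the exact log marginal for any (params, state)."""
    tau = state.tau
    logf = log_emission_table(params)
    logf_safe = np.where(np.isneginf(logf), _LOG_FLOOR, logf)
    C, S = _block_counts(net, tau)
    value = float(np.where(C > 0, C * logf_safe, 0.0).sum())
    if net.self_loops:
        Q = params.q_groups
        diag = logf_safe[:, np.arange(Q), np.arange(Q), :]  # (T, Q, M+1)
        value += float(np.where(S > 0, S * diag, 0.0).sum())
    log_alpha = _safe_log(params.alpha)
    log_pi = _safe_log(params.pi)
    steps = _present_steps(net.presence)
    for i, s in enumerate(steps):
        if s.size == 0:
            continue
        x0 = tau[i, s[0]]
        value += float(np.where(x0 > 0, x0 * log_alpha, 0.0).sum())
        value -= float(xlogy(x0, x0).sum())
        x = state.xi[i]
        if x.size:
            value += float(np.where(x > 0, x * log_pi[None, :, :], 0.0).sum())
            value -= float(xlogy(x, x).sum())
            marg = x.sum(axis=2)  # left marginals at steps s[0..K-2]
            value += float(xlogy(marg, marg).sum())
    return value


# ---------------------------------------------------------------------------
# the two VEM steps

def e_step(net: DynamicNetwork, params: DynSBMParams, state: VariationalState,
           max_inner: int = 5, tol: float = 1e-4) -> VariationalState:
    """Mean-field sweep(s): nodes visited in index order, each node's chain
    re-estimated exactly by forward–backward given the others' marginals."""
    new = state.copy()
    tau = new.tau
    Q = params.q_groups
    Yoh = _one_hot_values(net)
    logf = log_emission_table(params)
    logf_safe = np.where(np.isneginf(logf), _LOG_FLOOR, logf)
    log_alpha = _safe_log(params.alpha)
    log_pi = _safe_log(params.pi)
    steps = _present_steps(net.presence)
    for _ in range(max_inner):
        delta = 0.0
        for i in range(net.n_nodes):
            s = steps[i]
            if s.size == 0:
                continue
            msg = _node_messages(Yoh, tau, logf_safe, i, net.directed,
                                 net.self_loops, net.values)
            tau_i, xi_i = _forward_backward(log_alpha, log_pi, msg[s])
            delta = max(delta, float(np.abs(tau[i, s] - tau_i).max()))
            tau[i, s] = tau_i
            new.xi[i] = xi_i
        if delta < tol:
            break
    return new


def m_step(net: DynamicNetwork, state: VariationalState) -> DynSBMParams:
    """Closed-form maximizers of the expected complete log-likelihood, with
    additive smoothing EPS so empty groups keep valid positive parameters.
    Within-group (diagonal) emissions are pooled over time."""
    tau = state.tau
    Q = state.q_groups
    T, M = net.n_steps, net.n_categories
    steps = _present_steps(net.presence)

    a_num = np.zeros(Q)
    for i, s in enumerate(steps):
        if s.size:
            a_num += tau[i, s[0]]
    alpha = a_num + EPS
    alpha /= alpha.sum()

    x_num = np.zeros((Q, Q))
    for x in state.xi:
        if x.size:
            x_num += x.sum(axis=0)
    pi = x_num + EPS
    pi /= pi.sum(axis=1, keepdims=True)

    C, S = _block_counts(net, tau)          # C: (T, Q, Q, M+1), S: (T, Q, M+1)
    if net.self_loops:
        # self-loops use the diagonal block of their node's group
        C = C.copy()
        C[:, np.arange(Q), np.arange(Q), :] += S
    pos = C[..., 1:].sum(axis=3)            # (T, Q, Q) expected present edges
    den = C.sum(axis=3)                     # (T, Q, Q) expected observable dyads
    beta = (pos.transpose(1, 2, 0) + EPS) / (den.transpose(1, 2, 0) + 2 * EPS)
    pos_d = pos[:, np.arange(Q), np.arange(Q)].sum(axis=0)
    den_d = den[:, np.arange(Q), np.arange(Q)].sum(axis=0)
    beta[np.arange(Q), np.arange(Q), :] = \
        ((pos_d + EPS) / (den_d + 2 * EPS))[:, None]
    if not net.directed:
        beta = (beta + beta.transpose(1, 0, 2)) / 2.0

    gamma = None
    if M > 1:
        cat = C[..., 1:]                    # (T, Q, Q, M)
        gamma = (cat.transpose(1, 2, 0, 3) + EPS)
        gamma /= gamma.sum(axis=3, keepdims=True)
        cat_d = cat[:, np.arange(Q), np.arange(Q), :].sum(axis=0)  # (Q, M)
        gd = cat_d + EPS
        gd /= gd.sum(axis=1, keepdims=True)
        gamma[np.arange(Q), np.arange(Q), :, :] = gd[:, None, :]
        if not net.directed:
            gamma = (gamma + gamma.transpose(1, 0, 2, 3)) / 2.0
            gamma /= gamma.sum(axis=3, keepdims=True)
    return DynSBMParams(alpha, pi, beta, gamma, directed=net.directed,
                        self_loops=net.self_loops)


# ---------------------------------------------------------------------------
# fitting

def _state_from_memberships(net: DynamicNetwork, Zm: np.ndarray,
                            q: int) -> VariationalState:
    N, T = net.n_nodes, net.n_steps
    tau = np.zeros((N, T, q))
    xi: list[np.ndarray] = []
    for i in range(N):
        s = np.flatnonzero(net.presence[i])
        for t in s:
            tau[i, t, Zm[i, t] - 1] = 1.0
        x = np.zeros((max(s.size - 1, 0), q, q))
        for k in range(s.size - 1):
            x[k] = np.outer(tau[i, s[k]], tau[i, s[k + 1]])
        xi.append(x)
    return VariationalState(tau, xi)


def _initial_memberships(net: DynamicNetwork, q: int, n_init: int,
                         seed: int) -> list[np.ndarray]:
    """One spectral-flavoured k-means start on the time-aggregated adjacency,
    then random one-hot restarts."""
    rng = np.random.default_rng(seed)
    N, T = net.n_nodes, net.n_steps
    inits = []
    agg = (net.values > 0).sum(axis=0).astype(float)
    feats = np.hstack([agg, agg.T]) if net.directed else agg
    if q == 1:
        labels = np.zeros(N, dtype=np.int64)
    else:
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=q, n_init=10,
                    random_state=int(rng.integers(2 ** 31)))
        labels = km.fit_predict(feats)
    Z0 = np.where(net.presence, labels[:, None] + 1, 0)
    inits.append(Z0)
    for _ in range(max(n_init - 1, 0)):
        Zr = np.where(net.presence,
                      rng.integers(1, q + 1, size=(N, T)), 0)
        inits.append(Zr)
    return inits[:n_init]


def fit(net: DynamicNetwork, q_groups: int, n_init: int = 5,
        max_iter: int = 100, tol: float = 1e-6, seed: int = 0,
        max_inner: int = 5, inner_tol: float = 1e-4) -> FitResult:
    """Variational EM with restarts; returns the run with the best final ELBO.

    MAP membership trajectories come from a per-node Viterbi pass on the
    converged emission messages, so they respect the Markov chain rather
    than being pointwise argmaxes of tau.
    """
    if q_groups < 1:
        raise ValueError("q_groups must be >= 1")
    n_cells = int(net.presence.sum())
    if q_groups > n_cells:
        raise ValueError("more groups than present node-steps")
    best: tuple[float, VariationalState, DynSBMParams, list[float], bool, int] | None = None
    all_traces: list[list[float]] = []
    for init_Z in _initial_memberships(net, q_groups, n_init, seed):
        state = _state_from_memberships(net, init_Z, q_groups)
        params = m_step(net, state)
        trace: list[float] = []
        converged = False
        for it in range(max_iter):
            state = e_step(net, params, state, max_inner=max_inner, tol=inner_tol)
            params = m_step(net, state)
            L = elbo(net, params, state)
            trace.append(L)
            if it > 0 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
                converged = True
                break
        all_traces.append(trace)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], state, params, trace, converged, len(trace))
    _, state, params, trace, converged, n_iter = best

    # MAP trajectories: Viterbi on each node's chain at convergence
    Yoh = _one_hot_values(net)
    logf = log_emission_table(params)
    logf_safe = np.where(np.isneginf(logf), _LOG_FLOOR, logf)
    log_alpha = _safe_log(params.alpha)
    log_pi = _safe_log(params.pi)
    Zmap = np.zeros((net.n_nodes, net.n_steps), dtype=np.int64)
    for i in range(net.n_nodes):
        s = np.flatnonzero(net.presence[i])
        if s.size == 0:
            continue
        msg = _node_messages(Yoh, state.tau, logf_safe, i, net.directed,
                             net.self_loops, net.values)
        Zmap[i, s] = _viterbi(log_alpha, log_pi, msg[s]) + 1
    return FitResult(params, state,
                     MembershipTrajectories(Zmap, q_groups=q_groups),
                     trace, converged, n_iter, seed, all_traces=all_traces)
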