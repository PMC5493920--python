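"""Inference unit tests, built around independent oracles: a term-by-term
likelihood enumeration coded here (never sharing code with the package's
vectorized path) and exhaustive marginalization on tiny instances."""

import itertools
import math

import numpy as np
import pytest

from conftest import random_tiny_instance
from dynsbm import (DynSBMParams, DynamicNetwork, community_params,
                    complete_log_likelihood, e_step, elbo, exact_log_marginal,
                    fit, m_step, simulate)
from dynsbm.inference import _state_from_memberships


def oracle_loglik(net, Z, params):
    """Brute-force log P(Y, Z): explicit loops, scalar math only."""
    Zm = Z.Z if hasattr(Z, "Z") else np.asarray(Z)
    M = net.n_categories
    total = 0.0

    def log(p):
        return math.log(p) if p > 0 else -math.inf

    def emit(y, q, l, t):
        b = params.beta[q, l, t]
        if y == 0:
            return log(1.0 - b)
        if M == 1:
            return log(b)
        return log(b) + log(params.gamma[q, l, t, y - 1])

    for i in range(net.n_nodes):
        steps = [t for t in range(net.n_steps) if net.presence[i, t]]
        if not steps:
            continue
        total += log(params.alpha[Zm[i, steps[0]] - 1])
        for a, b_ in zip(steps, steps[1:]):
            total += log(params.pi[Zm[i, a] - 1, Zm[i, b_] - 1])
    for t in range(net.n_steps):
        for i in range(net.n_nodes):
            for j in range(net.n_nodes):
                if not (net.presence[i, t] and net.presence[j, t]):
                    continue
                if i == j:
                    if net.self_loops:
                        q = Zm[i, t] - 1
                        total += emit(net.values[t, i, i], q, q, t)
                    continue
                if not net.directed and j < i:
                    continue
                total += emit(net.values[t, i, j], Zm[i, t] - 1,
                              Zm[j, t] - 1, t)
    return total


class TestCompleteLogLikelihood:
    def test_single_dyad_bernoulli(self):
        net = DynamicNetwork(np.array([[[0, 1], [1, 0]]]),
                             np.ones((2, 1), bool), False, False, 1)
        p = DynSBMParams(np.array([1.0]), np.array([[1.0]]),
                         np.array([[[0.5]]]))
        assert complete_log_likelihood(net, np.ones((2, 1), int), p) == \
            pytest.approx(math.log(0.5), abs=1e-12)

    def test_forbidden_transition_is_minus_inf(self):
        p = DynSBMParams(np.array([0.5, 0.5]), np.eye(2),
                         np.full((2, 2, 2), 0.5))
        net, Z = simulate(p, np.ones((3, 2), bool), seed=0)
        Zbad = Z.Z.copy()
        Zbad[0, 1] = 3 - Zbad[0, 0]  # switch under an identity chain
        assert complete_log_likelihood(net, Zbad, p) == -math.inf

    @pytest.mark.parametrize("m", [1, 3])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_term_enumeration_oracle(self, m, seed):
        net, Z, params = random_tiny_instance(seed, n=4, t=2, q=2, m=m)
        assert complete_log_likelihood(net, Z, params) == \
            pytest.approx(oracle_loglik(net, Z, params), abs=1e-10)

    def test_directed_self_loop_instance(self):
        beta = np.stack([np.array([[0.6, 0.2], [0.4, 0.6]])] * 2, axis=2)
        p = DynSBMParams(np.array([0.4, 0.6]),
                         np.array([[0.8, 0.2], [0.3, 0.7]]), beta,
                         directed=True, self_loops=True)
        net, Z = simulate(p, np.ones((4, 2), bool), seed=5)
        assert complete_log_likelihood(net, Z, p) == \
            pytest.approx(oracle_loglik(net, Z, p), abs=1e-10)


class TestExactLogMarginal:
    def test_single_group_equals_complete(self, tiny):
        net, Z, _ = tiny
        p = community_params(q=1, n_steps=net.n_steps, beta_within=0.4,
                             beta_between=0.4)
        Z1 = np.where(net.presence, 1, 0)
        assert exact_log_marginal(net, p) == \
            pytest.approx(complete_log_likelihood(net, Z1, p), abs=1e-10)

    def test_two_node_hand_sum(self):
        # N=2, T=1, Q=2: marginal = sum over 4 configurations
        net = DynamicNetwork(np.array([[[0, 1], [1, 0]]]),
                             np.ones((2, 1), bool), False, False, 1)
        beta = np.array([[[0.8], [0.3]], [[0.3], [0.6]]])
        p = DynSBMParams(np.array([0.5, 0.5]), np.eye(2), beta)
        hand = (0.25 * 0.8) + (0.25 * 0.3) + (0.25 * 0.3) + (0.25 * 0.6)
        assert exact_log_marginal(net, p) == pytest.approx(math.log(hand),
                                                           abs=1e-12)

    def test_refuses_large_instances(self):
        p = community_params(q=3, n_steps=10)
        net, _ = simulate(p, np.ones((30, 10), bool), seed=0)
        with pytest.raises(ValueError, match="too large"):
            exact_log_marginal(net, p)


class TestEStep:
    def test_single_group_is_degenerate(self, tiny):
        net, Z, _ = tiny
        p = community_params(q=1, n_steps=net.n_steps, beta_within=0.4,
                             beta_between=0.4)
        state = _state_from_memberships(net, np.where(net.presence, 1, 0), 1)
        new = e_step(net, p, state)
        assert np.allclose(new.tau[net.presence], 1.0)
        assert all(np.allclose(x, 1.0) for x in new.xi if x.size)

    def test_group_swap_symmetry_preserved(self):
        p = community_params(q=2, n_steps=2, beta_within=0.5,
                             beta_between=0.5, pi_stay=0.5)
        net, _ = simulate(p, np.ones((6, 2), bool), seed=1)
        state = _state_from_memberships(net, np.ones((6, 2), int), 2)
        state.tau[:] = 0.5
        for x in state.xi:
            x[:] = 0.25
        new = e_step(net, p, state, max_inner=3)
        # parameters are invariant under swapping groups, so tau must stay so
        assert np.allclose(new.tau[..., 0], new.tau[..., 1], atol=1e-12)

    def test_first_node_update_is_exact_conditional(self):
        net, Z, params = random_tiny_instance(3, n=4, t=2, q=2, m=1)
        state = _state_from_memberships(net, Z.Z, 2)
        new = e_step(net, params, state, max_inner=1)
        # enumerate P(z_0 | Y, z_-0) with the other nodes fixed one-hot
        lls = {}
        for traj in itertools.product([1, 2], repeat=net.n_steps):
            Zc = Z.Z.copy()
            Zc[0] = traj
            lls[traj] = complete_log_likelihood(net, Zc, params)
        mx = max(lls.values())
        w = {k: math.exp(v - mx) for k, v in lls.items()}
        tot = sum(w.values())
        for t in range(net.n_steps):
            for g in (1, 2):
                expect = sum(v for k, v in w.items() if k[t] == g) / tot
                assert new.tau[0, t, g - 1] == pytest.approx(expect, abs=1e-8)


class TestMStep:
    def test_block_density_from_hard_memberships(self):
        params = community_params(q=2, n_steps=3, beta_within=0.7,
                                  beta_between=0.2, pi_stay=1.0)
        net, Z = simulate(params, np.ones((40, 3), bool), seed=4)
        state = _state_from_memberships(net, Z.Z, 2)
        est = m_step(net, state)
        for t in range(3):
            g = Z.Z[:, t]
            a, b = np.flatnonzero(g == 1), np.flatnonzero(g == 2)
            dens = (net.values[t][np.ix_(a, b)] > 0).mean()
            assert est.beta[0, 1, t] == pytest.approx(dens, abs=1e-4)

    def test_transition_counts_with_smoothing(self):
        # one observed 1->2 switch among n transitions from group 1
        eps = 1e-6
        n = 9
        Zm = np.ones((1, n + 1), dtype=int)
        Zm[0, -1] = 2
        vals = np.zeros((n + 1, 2, 2), dtype=int)
        net = DynamicNetwork(vals, np.ones((2, n + 1), bool), False, False, 1)
        Zfull = np.vstack([Zm, Zm])
        state = _state_from_memberships(net, Zfull, 2)
        est = m_step(net, state)
        n_trans = 2 * n  # two identical nodes
        stay = (2 * (n - 1) + eps) / (2 * n + 2 * eps)
        assert est.pi[0, 0] == pytest.approx(stay, rel=1e-9)
        assert est.pi[0, 1] == pytest.approx(1 - stay, rel=1e-6)

    def test_outputs_are_valid_stochastic_objects(self):
        net, Z, params = random_tiny_instance(7, n=5, t=3, q=2, m=3)
        state = _state_from_memberships(net, Z.Z, 2)
        state = e_step(net, params, state)
        est = m_step(net, state)
        est.validate()  # raises on any violated constraint

    def test_local_optimality_probe(self):
        net, Z, params = random_tiny_instance(11, n=5, t=2, q=2, m=1)
        state = e_step(net, params, _state_from_memberships(net, Z.Z, 2))
        est = m_step(net, state)
        base = elbo(net, est, state)
        rng = np.random.default_rng(0)
        for _ in range(100):
            alpha = np.abs(est.alpha + rng.uniform(-0.01, 0.01, 2))
            alpha /= alpha.sum()
            pi = np.abs(est.pi + rng.uniform(-0.01, 0.01, (2, 2)))
            pi /= pi.sum(axis=1, keepdims=True)
            d = rng.uniform(-0.01, 0.01)
            beta = np.clip(est.beta + d, 1e-6, 1 - 1e-6)
            beta[0, 0] = beta[0, 0, 0]
            beta[1, 1] = beta[1, 1, 0]
            beta = (beta + beta.transpose(1, 0, 2)) / 2
            pert = DynSBMParams(alpha, pi, beta)
            assert elbo(net, pert, state) <= base + 1e-9


class TestFit:
    def test_single_group_gives_pooled_density_and_tight_bound(self, tiny):
        net, _, _ = tiny
        fr = fit(net, 1, n_init=1, max_iter=20, seed=0)
        pooled = np.mean([
            (net.values[t][np.triu_indices(net.n_nodes, k=1)] > 0).mean()
            for t in range(net.n_steps)])
        assert fr.params.beta[0, 0, 0] == pytest.approx(pooled, abs=1e-4)
        assert fr.elbo == pytest.approx(exact_log_marginal(net, fr.params),
                                        abs=1e-8)

    def test_elbo_below_exact_marginal(self, planted_small):
        net, _, _ = planted_small
        fr = fit(net, 2, n_init=3, max_iter=100, seed=1)
        assert fr.elbo <= exact_log_marginal(net, fr.params) + 1e-9

    def test_elbo_trace_monotone(self, planted_small):
        net, _, _ = planted_small
        fr = fit(net, 2, n_init=4, max_iter=100, seed=5)
        for trace in fr.all_traces:
            tr = np.asarray(trace)
            assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))

    def test_map_respects_group_zero_convention(self):
        beta = np.stack([np.array([[0.6, 0.2], [0.4, 0.6]])] * 3, axis=2)
        p = DynSBMParams(np.array([0.5, 0.5]),
                         np.array([[0.8, 0.2], [0.3, 0.7]]), beta,
                         directed=True, self_loops=True)
        presence = np.ones((6, 3), bool)
        presence[0, 1] = presence[3, 2] = False
        net, Z = simulate(p, presence, seed=2)
        fr = fit(net, 2, n_init=2, max_iter=30, seed=0)
        assert np.array_equal(fr.map_memberships.Z == 0, ~presence)

    def test_too_many_groups_rejected(self, tiny):
        net, _, _ = tiny
        with pytest.raises(ValueError, match="groups"):
            fit(net, net.presence.sum() + 1)

    def test_deterministic_given_seed(self, planted_small):
        net, _, _ = planted_small
        a = fit(net, 2, n_init=2, max_iter=30, seed=9)
        b = fit(net, 2, n_init=2, max_iter=30, seed=9)
        assert a.elbo_trace == b.elbo_trace
        assert np.array_equal(a.map_memberships.Z, b.map_memberships.Z)


class TestInvariances:
    def test_label_permutation_invariance(self):
        net, Z, params = random_tiny_instance(13, n=4, t=2, q=2, m=3)
        state = e_step(net, params, _state_from_memberships(net, Z.Z, 2))
        perm = [1, 0]
        p2 = DynSBMParams(params.alpha[perm], params.pi[np.ix_(perm, perm)],
                          params.beta[np.ix_(perm, perm)],
                          params.gamma[np.ix_(perm, perm)])
        s2 = state.copy()
        s2.tau = s2.tau[:, :, perm]
        s2.xi = [x[:, perm][:, :, perm] for x in s2.xi]
        Z2 = np.where(Z.Z > 0, 3 - Z.Z, 0)
        assert complete_log_likelihood(net, Z2, p2) == \
            pytest.approx(complete_log_likelihood(net, Z, params), abs=1e-10)
        assert elbo(net, p2, s2) == pytest.approx(elbo(net, params, state),
                                                  abs=1e-10)

    def test_absent_nodes_do_not_contribute(self):
        net, Z, params = random_tiny_instance(17, n=4, t=2, q=2, m=1)
        state = e_step(net, params, _state_from_memberships(net, Z.Z, 2))
        base = elbo(net, params, state)
        # append two nodes absent everywhere
        vals = np.zeros((net.n_steps, 6, 6), dtype=int)
        vals[:, :4, :4] = net.values
        presence = np.vstack([net.presence, np.zeros((2, net.n_steps), bool)])
        net2 = DynamicNetwork(vals, presence, net.directed, net.self_loops,
                              net.n_categories)
        tau2 = np.zeros((6, net.n_steps, 2))
        tau2[:4] = state.tau
        from dynsbm import VariationalState
        s2 = VariationalState(tau2, state.xi + [np.zeros((0, 2, 2))] * 2)
        assert elbo(net2, params, s2) == pytest.approx(base, abs=1e-10)
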