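import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polisoc import (SocietyState, choice_probability,
                     group_payoff_given_status,
                     individual_payoff_given_action, individual_payoffs,
                     group_payoffs, make_params, revise_groups,
                     revise_individuals)

from .conftest import random_state
from .helpers import oracle_payoffs


class TestChoiceProbability:
    def test_infinite_precision_is_argmax(self):
        assert choice_probability(0.3, math.inf) == 1.0
        assert choice_probability(-0.3, math.inf) == 0.0
        assert choice_probability(0.0, math.inf) == 0.5

    def test_zero_precision_is_uniform(self):
        for delta in (-5.0, 0.0, 5.0):
            assert choice_probability(delta, 0.0) == 0.5

    def test_logit_symmetry_at_zero(self):
        assert choice_probability(0.0, 1.0) == 0.5

    @given(delta=st.floats(-50, 50), lam=st.floats(0, 100))
    @settings(max_examples=100, derandomize=True)
    def test_complementarity_and_monotonicity(self, delta, lam):
        p = choice_probability(delta, lam)
        q = choice_probability(-delta, lam)
        assert p + q == pytest.approx(1.0)
        assert choice_probability(delta + 1.0, lam) >= p

    def test_extreme_arguments_do_not_overflow(self):
        assert choice_probability(-1e6, 10.0) == 0.0
        assert choice_probability(1e6, 10.0) == 1.0


class TestHypotheticalPayoffs:
    def test_noop_action_equals_realized(self, micro_params):
        state = random_state(micro_params, np.random.default_rng(3))
        pi = individual_payoffs(state, micro_params)
        for j in range(micro_params.G):
            for i in range(micro_params.group_sizes[j]):
                idx = micro_params.offsets[j] + i
                got = individual_payoff_given_action(
                    state, j, i, int(state.x[idx]), micro_params)
                assert got == pytest.approx(pi[idx])

    def test_noop_status_equals_realized(self, micro_params):
        state = random_state(micro_params, np.random.default_rng(4))
        rec = group_payoffs(state, micro_params)
        for j in range(micro_params.G):
            got = group_payoff_given_status(state, j, int(state.theta[j]),
                                            micro_params)
            assert got == pytest.approx(rec.Pi[j])

    def test_sole_contributor_quitting_forces_defection(self, micro_params):
        # i is the only contributor of a cooperating group: a=0 leaves the
        # group with no effort, so it is evaluated outside the coalition
        # producing nothing -> baseline endowment only
        x = np.array([1, 0, 0, 1, 1, 0], np.int8)
        state = SocietyState(x=x, theta=np.array([1, 1], np.int8),
                             f=np.array([0.5, 0.5]))
        got = individual_payoff_given_action(state, 0, 0, 0, micro_params)
        assert got == pytest.approx(micro_params.pi0)

    def test_sole_cooperator_defection_uses_own_production(self,
                                                           micro_params):
        x = np.array([1, 1, 0, 1, 0, 0], np.int8)
        state = SocietyState(x=x, theta=np.array([1, 0], np.int8),
                             f=np.array([0.5, 0.5]))
        got = group_payoff_given_status(state, 0, 0, micro_params)
        P = micro_params.B1 * 2 / (2 + micro_params.X0)
        expected = micro_params.Pi0[0] - micro_params.c * 2 + P
        assert got == pytest.approx(expected)

    def test_joining_empty_coalition_takes_full_share(self, micro_params):
        x = np.array([1, 1, 0, 1, 0, 0], np.int8)
        state = SocietyState(x=x, theta=np.array([0, 0], np.int8),
                             f=np.array([0.5, 0.5]))
        got = group_payoff_given_status(state, 0, 1, micro_params)
        P = micro_params.B1 * 2 / (2 + micro_params.X0)
        Q = micro_params.B2 * P / (P + micro_params.Z0)
        expected = micro_params.Pi0[0] - micro_params.c * 2 + Q  # v = 1
        assert got == pytest.approx(expected)


def _oracle_best_action_individual(state, params, j, i):
    """Argmax over both actions via a from-scratch payoff evaluation."""
    payoffs = []
    for a in (0, 1):
        x = state.x.copy()
        x[params.offsets[j] + i] = a
        x_groups = [x[params.offsets[k]:params.offsets[k]
                      + params.group_sizes[k]].tolist()
                    for k in range(params.G)]
        _, pi = oracle_payoffs(x_groups, state.theta.tolist(),
                               state.f.tolist(), params.B1, params.X0,
                               params.B2, params.Z0, params.c, params.pi0,
                               params.alpha, params.group_sizes)
        payoffs.append(pi[j][i])
    if payoffs[1] > payoffs[0]:
        return {1}
    if payoffs[1] < payoffs[0]:
        return {0}
    return {0, 1}


def _oracle_best_status_group(state, params, j):
    payoffs = []
    for s in (0, 1):
        theta = state.theta.copy()
        theta[j] = s
        x_groups = [state.x[params.offsets[k]:params.offsets[k]
                            + params.group_sizes[k]].tolist()
                    for k in range(params.G)]
        Pi, _ = oracle_payoffs(x_groups, theta.tolist(), state.f.tolist(),
                               params.B1, params.X0, params.B2, params.Z0,
                               params.c, params.pi0, params.alpha,
                               params.group_sizes)
        payoffs.append(Pi[j])
    if payoffs[1] > payoffs[0]:
        return {1}
    if payoffs[1] < payoffs[0]:
        return {0}
    return {0, 1}


def _micro_societies(n_states: int, seed: int):
    """Random micro-societies (G <= 3, n <= 4) with valid states."""
    rng = np.random.default_rng(seed)
    for _ in range(n_states):
        G = int(rng.integers(2, 4))
        n = int(rng.integers(2, 5))
        params = make_params(dict(
            G=G, n=n, B1=float(rng.uniform(10, 80)), X0=5.0,
            B2=float(rng.uniform(0, 200)), Z0=50.0, c=1.0, pi0=1.0,
            alpha=float(rng.choice([0.0, 0.5, 1.0])),
            epsilon=float(rng.uniform(0, 1)), mu1=1.0, mu2=1.0,
            lam=math.inf))
        yield params, random_state(params, rng)


def test_individual_revision_matches_bruteforce_argmax():
    """At infinite precision every revised contribution is a best response.

    For random micro-societies, each individual's chosen action must equal
    the argmax of both hypothetical payoffs computed by an independent
    from-scratch evaluation of the full payoff chain (ties accept either).
    """
    for params, state in _micro_societies(60, seed=202):
        new_x = revise_individuals(state, params, np.random.default_rng(7))
        for j in range(params.G):
            for i in range(params.group_sizes[j]):
                idx = params.offsets[j] + i
                allowed = _oracle_best_action_individual(state, params, j, i)
                assert int(new_x[idx]) in allowed, (params, j, i)


def test_group_revision_matches_bruteforce_argmax():
    """Revised group statuses equal the from-scratch argmax (membership
    rule forcing effortless groups out of the coalition)."""
    for params, state in _micro_societies(60, seed=303):
        new_theta = revise_groups(state, params, np.random.default_rng(8))
        X = state.group_efforts(params)
        for j in range(params.G):
            if X[j] == 0:
                assert new_theta[j] == 0
                continue
            allowed = _oracle_best_status_group(state, params, j)
            assert int(new_theta[j]) in allowed, (params, j)


class TestRevisionMechanics:
    def test_no_selection_keeps_strategies(self, micro_params):
        params = micro_params.with_(mu1=0.0, mu2=0.0)
        state = random_state(params, np.random.default_rng(5))
        rng = np.random.default_rng(0)
        assert np.array_equal(revise_individuals(state, params, rng),
                              state.x)
        state2 = random_state(params, np.random.default_rng(6))
        state2.x[:3] = 1  # all groups keep effort -> statuses untouched
        rng = np.random.default_rng(0)
        assert np.array_equal(revise_groups(state2, params, rng),
                              state2.theta)

    def test_fixed_seed_reproducible(self, micro_params):
        state = random_state(micro_params, np.random.default_rng(9))
        a = revise_individuals(state, micro_params,
                               np.random.default_rng(123))
        b = revise_individuals(state, micro_params,
                               np.random.default_rng(123))
        assert np.array_equal(a, b)

    def test_dominant_contribution_adopted_by_all(self):
        # large per-capita benefit, small group: contributing dominates
        params = make_params(dict(G=2, n=2, B1=100.0, X0=5.0, B2=0.0,
                                  Z0=50.0, c=1.0, pi0=1.0, alpha=0.0,
                                  epsilon=0.0, mu1=1.0, mu2=1.0,
                                  lam=math.inf))
        state = SocietyState(x=np.zeros(4, np.int8),
                             theta=np.zeros(2, np.int8),
                             f=np.array([0.5, 0.5]))
        # marginal gain of the first unit: P(1) - P(0) = 100/6 > c = 1
        new_x = revise_individuals(state, params, np.random.default_rng(1))
        assert new_x.tolist() == [1, 1, 1, 1]

    def test_profitable_coalition_adopted_by_both_groups(self):
        params = make_params(dict(G=2, n=2, B1=40.0, X0=5.0, B2=500.0,
                                  Z0=10.0, c=1.0, pi0=1.0, alpha=1.0,
                                  epsilon=0.0, mu1=1.0, mu2=1.0,
                                  lam=math.inf))
        state = SocietyState(x=np.ones(4, np.int8),
                             theta=np.zeros(2, np.int8),
                             f=np.array([0.5, 0.5]))
        # each P = 40*2/7 = 11.4; joining alone already pays:
        # Q(P) = 500*11.4/21.4 = 266 > P, so theta -> (1, 1)
        new_theta = revise_groups(state, params, np.random.default_rng(2))
        assert new_theta.tolist() == [1, 1]
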