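"""Strategy revision by myopic best response with logit errors.

Each step, every individual is independently selected for revision with
probability ``mu1`` and every group with probability ``mu2``. A selected
actor compares the payoffs of its two actions against the *pre-revision*
state — all other actors' strategies and all powers held fixed, with no
anticipation of the power consequences — and draws its new action from the
logit (quantal-response) rule with precision ``lam``. All selected
individuals update simultaneously, then all selected groups.

The membership rule (a group with zero effort can never sit in the
coalition) is enforced inside every hypothetical: an individual whose
withdrawal would empty its group's effort evaluates that branch with the
group as a defector producing nothing, and a group cannot adopt
cooperation while its effort is zero.

Randomness contract: selection uniforms are drawn for all actors first
(flat canonical order: group index, then member index), then action
uniforms for all actors, one draw each whether or not selected. This makes
runs bit-reproducible from a seed and the outcome independent of the order
in which actors are evaluated.
"""

from __future__ import annotations

import math

import numpy as np

from .games import (coalition_production, group_payoffs, group_production,
                    individual_payoffs, power_shares)
from .model_state import ModelParams, SocietyState

__all__ = [
    "individual_payoff_given_action",
    "group_payoff_given_status",
    "choice_probability",
    "revise_individuals",
    "revise_groups",
    "enforce_membership_rule",
]


def individual_payoff_given_action(state: SocietyState, j: int, i: int,
                                   action: int, params: ModelParams) -> float:
    """Hypothetical payoff of member ``i`` of group ``j`` playing ``action``.

    Recomputes the full chain of both economic games on the modified state
    (other individuals' actions, all group statuses and powers fixed): the
    group's production, the coalition pool and club good, and the member's
    share. If the change leaves the group with zero effort, the group is
    evaluated as a defector.
    """
    hyp = state.copy()
    idx = params.offsets[j] + i
    hyp.x[idx] = action
    enforce_membership_rule(hyp, params)
    return float(individual_payoffs(hyp, params)[idx])


def group_payoff_given_status(state: SocietyState, j: int, status: int,
                              params: ModelParams) -> float:
    """Hypothetical total payoff of group ``j`` with status ``status``.

    Other groups' statuses, all contributions and powers are held fixed;
    the coalition pool, club good and shares are recomputed for the
    hypothetical coalition. Cooperation with zero group effort is forced
    back to defection (membership rule).
    """
    hyp = state.copy()
    hyp.theta[j] = status
    enforce_membership_rule(hyp, params)
    return float(group_payoffs(hyp, params).Pi[j])


def choice_probability(delta: float, lam: float) -> float:
    """Logit probability of the higher-indexed action given payoff gap.

    ``p = 1 / (1 + exp(-lam * delta))`` with ``delta`` the payoff of action
    1 minus that of action 0. At infinite precision the rule is the exact
    best response with ties broken by a fair coin.
    """
    if math.isinf(lam):
        if delta > 0:
            return 1.0
        if delta < 0:
            return 0.0
        return 0.5
    # guard the exp against overflow for large finite lam * |delta|
    z = -lam * delta
    if z > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def enforce_membership_rule(state: SocietyState, params: ModelParams) -> None:
    """Force theta_j = 0 wherever the group effort X_j is zero (in place)."""
    X = state.group_efforts(params)
    state.theta[X == 0] = 0


def _individual_deltas(state: SocietyState, params: ModelParams) -> np.ndarray:
    """Payoff gain of contributing vs not, per individual (flat array).

    Equivalent to two calls of :func:`individual_payoff_given_action` per
    individual but computed incrementally: only the focal group's
    production and, for coalition members, the club-good pool change.
    """
    X = state.group_efforts(params)
    P = group_production(X, params.B1, params.X0)
    coop = state.theta == 1
    Z = float(P[coop].sum())
    if coop.any():
        v = power_shares(state.f, state.theta)
    else:
        v = np.zeros(params.G)

    deltas = np.empty(params.total_n)
    pos = 0
    for j in range(params.G):
        n_j = params.group_sizes[j]
        xj = state.x[pos:pos + n_j].astype(float)
        X_others = X[j] - xj  # effort of the group without the focal member
        na = params.n_alpha[j]
        term = np.empty((2, n_j))
        for a in (0, 1):
            X_hyp = X_others + a
            P_hyp = group_production(X_hyp, params.B1, params.X0)
            if coop[j]:
                # group drops out of the coalition where its effort is zero
                Z_hyp = Z - P[j] + P_hyp
                Q_hyp = params.B2 * Z_hyp / (Z_hyp + params.Z0)
                res = np.where(X_hyp > 0, v[j] * Q_hyp, 0.0)
            else:
                res = P_hyp
            term[a] = -params.c * a + res / na
        deltas[pos:pos + n_j] = term[1] - term[0]
        pos += n_j
    return deltas


def _group_status_payoffs(state: SocietyState, params: ModelParams
                          ) -> np.ndarray:
    """Hypothetical total payoff of each group under both statuses.

    Returns an array of shape (2, G): row ``s`` holds each group's payoff
    with its own status set to ``s`` and everything else fixed. A group
    with zero effort has its cooperate row forced to the defect value.
    """
    X = state.group_efforts(params)
    P = group_production(X, params.B1, params.X0)
    coop = state.theta == 1
    Z = float(P[coop].sum())
    F = float(state.f[coop].sum())

    base = params.Pi0 - params.c * X
    defect = base + P
    out = np.vstack([defect, defect.copy()])
    for j in range(params.G):
        if X[j] == 0:
            continue  # membership rule: cooperate branch unavailable
        if coop[j]:
            Z_in, F_in = Z, F
        else:
            Z_in, F_in = Z + P[j], F + state.f[j]
        Q = coalition_production(Z_in, params.B2, params.Z0)
        if F_in > 0:
            v_j = state.f[j] / F_in
        else:
            # power-degenerate coalition: equal shares
            C_in = int(coop.sum()) + (0 if coop[j] else 1)
            v_j = 1.0 / C_in
        out[1, j] = base[j] + v_j * Q
    return out


def revise_individuals(state: SocietyState, params: ModelParams,
                       rng: np.random.Generator) -> np.ndarray:
    """One synchronous round of individual strategy revision; returns new x.

    Every individual is selected with probability ``mu1``; selected ones
    evaluate both actions against the same pre-revision state and draw the
    new action from the logit rule. Non-selected individuals keep theirs.
    """
    N = params.total_n
    select_u = rng.random(N)
    action_u = rng.random(N)
    new_x = state.x.copy()
    selected = select_u < params.mu1
    if not selected.any():
        return new_x
    deltas = _individual_deltas(state, params)
    for idx in np.flatnonzero(selected):
        p1 = choice_probability(float(deltas[idx]), params.lam)
        new_x[idx] = 1 if action_u[idx] < p1 else 0
    return new_x


def revise_groups(state: SocietyState, params: ModelParams,
                  rng: np.random.Generator) -> np.ndarray:
    """One synchronous round of group status revision; returns new theta.

    Selected groups evaluate both statuses against the same pre-revision
    coalition. The membership rule is applied to the result: theta_j = 0
    wherever X_j = 0, whatever was drawn.
    """
    G = params.G
    select_u = rng.random(G)
    action_u = rng.random(G)
    new_theta = state.theta.copy()
    selected = select_u < params.mu2
    if selected.any():
        payoffs = _group_status_payoffs(state, params)
        for j in np.flatnonzero(selected):
            delta = float(payoffs[1, j] - payoffs[0, j])
            p1 = choice_probability(delta, params.lam)
            new_theta[j] = 1 if action_u[j] < p1 else 0
    X = state.group_efforts(params)
    new_theta[X == 0] = 0
    return new_theta
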