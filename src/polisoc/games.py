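"""Pure payoff functions for the economic and political games.

Within each group a nonlinear public-goods game converts the combined
effort ``X_j`` into a resource ``P_j`` with saturating returns. Cooperating
groups ("elites") pool their production into a club good ``Q`` divided in
proportion to power; defecting groups ("counter-elites") keep their own
production. Powers then evolve by a Tullock contest over effective
political efforts ``y_j = Pi_j * (1 - eps + eps * f_j)``.

All functions here are side-effect free; the simulator composes them, and
the decision module's brute-force oracle reuses them.
"""

from __future__ import annotations

import numpy as np

from .model_state import ModelParams, SocietyState, StepRecord

__all__ = [
    "group_production",
    "coalition_production",
    "power_shares",
    "group_payoffs",
    "individual_payoffs",
    "effective_effort",
    "update_power",
    "play_games",
]


def group_production(X, B1: float, X0: float):
    """Within-group production P = B1 * X / (X + X0).

    Saturating (half-effort at ``X = X0``), strictly increasing and concave
    in ``X``; ``X = 0`` yields 0.
    """
    X = np.asarray(X, dtype=float)
    out = B1 * X / (X + X0)
    return float(out) if out.ndim == 0 else out


def coalition_production(Z: float, B2: float, Z0: float) -> float:
    """Between-group production Q = B2 * Z / (Z + Z0)."""
    return B2 * Z / (Z + Z0)


def power_shares(f: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Share of the club good per group: relative power within the coalition.

    ``v_j = f_j / sum_{k cooperating} f_k`` for cooperators, 0 for
    defectors. A coalition whose total power is exactly zero (a transient,
    power-degenerate corner) receives equal shares ``1/C`` — the symmetric
    limit of the rule.

    Raises
    ------
    ValueError
        If no group cooperates (shares are undefined).
    """
    f = np.asarray(f, float)
    theta = np.asarray(theta)
    coop = theta == 1
    C = int(coop.sum())
    if C == 0:
        raise ValueError("power shares undefined for an empty coalition")
    v = np.zeros_like(f)
    F = f[coop].sum()
    if F > 0:
        v[coop] = f[coop] / F
    else:
        v[coop] = 1.0 / C
    return v


def group_payoffs(state: SocietyState, params: ModelParams, t: int = 0
                  ) -> StepRecord:
    """Play both economic games and return the realized per-group record.

    Total group payoff: ``Pi_j = n_j*pi0 - c*X_j + P_j`` for defectors and
    ``Pi_j = n_j*pi0 - c*X_j + v_j*Q`` for coalition members.
    """
    X = state.group_efforts(params)
    P = group_production(X, params.B1, params.X0)
    coop = state.theta == 1
    C = int(coop.sum())
    Z = float(P[coop].sum())
    if C > 0:
        Q = coalition_production(Z, params.B2, params.Z0)
        v = power_shares(state.f, state.theta)
    else:
        Q = 0.0
        v = np.zeros(params.G)
    resource = np.where(coop, v * Q, P)
    Pi = params.Pi0 - params.c * X + resource
    return StepRecord(t=t, X=X, P=P, C=C, Z=Z, Q=Q, v=v, Pi=Pi,
                      y=None, theta=state.theta.copy(), f=state.f.copy())


def individual_payoffs(state: SocietyState, params: ModelParams,
                       record: StepRecord | None = None) -> np.ndarray:
    """Per-individual payoffs pi_ij (flat array, groups concatenated).

    Each member receives a ``1/n_j**alpha`` share of its group's resource
    term (``P_j`` if the group defects, ``v_j*Q`` if it cooperates), minus
    the contribution cost if it contributed.
    """
    if record is None:
        record = group_payoffs(state, params)
    coop = state.theta == 1
    resource = np.where(coop, record.v * record.Q, record.P)
    per_capita = resource / params.n_alpha
    per_capita_flat = np.repeat(per_capita, params.group_sizes)
    return params.pi0 - params.c * state.x.astype(float) + per_capita_flat


def effective_effort(Pi, f, epsilon: float):
    """Effective political effort y = Pi * (1 - eps + eps * f).

    At ``eps = 0`` effort equals material payoff; at ``eps = 1`` payoff and
    power combine multiplicatively. Requires ``Pi >= 0`` (guaranteed by the
    parameter bound ``c <= pi0``); raises otherwise since the contest is
    undefined for negative efforts.
    """
    Pi = np.asarray(Pi, float)
    if (Pi < 0).any():
        raise ValueError("negative group payoff: political effort undefined")
    out = Pi * (1.0 - epsilon + epsilon * np.asarray(f, float))
    return float(out) if out.ndim == 0 else out


def update_power(y: np.ndarray, G: int) -> np.ndarray:
    """Tullock contest: f'_j = y_j / sum_k y_k, or 1/G if all efforts are 0."""
    y = np.asarray(y, float)
    if (y < 0).any():
        raise ValueError("negative effort: Tullock contest undefined")
    total = y.sum()
    if total > 0:
        return y / total
    return np.full(G, 1.0 / G)


def play_games(state: SocietyState, params: ModelParams, t: int = 0
               ) -> StepRecord:
    """Play the economic games then the political contest; full StepRecord."""
    record = group_payoffs(state, params, t=t)
    record.y = effective_effort(record.Pi, state.f, params.epsilon)
    record.f_next = update_power(record.y, params.G)
    return record
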