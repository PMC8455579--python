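"""Closed-form equilibrium approximations and stability conditions.

Treating individual contributions as continuous gives closed-form
approximations for the stationary group effort in an isolated group
(``X*``) and in a symmetric coalition of ``C`` identical cooperating
groups (``X_c*``), together with existence conditions for the
no-cooperation state and the no-defection condition for coalition
members. For the full coalition (C = G) the upper incumbency bound
``eps_max`` has a closed form; for partial coalitions the bounds are only
implicit, and a numerical power-stability probe (frozen strategies,
perturb-one-power, iterate the contest map) stands in for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .games import coalition_production, group_production, play_games
from .model_state import ModelParams, SocietyState

__all__ = [
    "EquilibriumPrediction",
    "single_group_effort",
    "positive_effort_condition",
    "no_cooperation_exists",
    "symmetric_coalition_effort",
    "no_defection_condition",
    "eps_max_full_coalition",
    "symmetric_coalition_state",
    "power_stability_probe",
    "eps_max_numeric",
    "stability_region_scan",
]


@dataclass
class EquilibriumPrediction:
    """Analytic verdict for one hypothesized symmetric equilibrium."""

    C: int
    X_star: float
    exists: bool
    stable: bool | None = None      # None when exists is False
    eps_min: float | None = None
    eps_max: float | None = None
    A_c: float | None = None
    Q_G: float | None = None


def single_group_effort(R1: float, n: int, alpha: float, X0: float) -> float:
    """Stationary effort X* of an isolated group (continuous approximation).

    ``X* = 0`` when ``R1 < n**alpha``; otherwise
    ``X* = min(n, X0 * (sqrt(R1 / n**alpha) - 1))``.
    """
    na = n ** alpha
    if R1 < na:
        return 0.0
    return min(float(n), X0 * (math.sqrt(R1 / na) - 1.0))


def positive_effort_condition(b1: float, c: float, X0: float) -> bool:
    """Strictly positive within-group effort requires b1 > c * (1 + X0)."""
    return b1 > c * (1.0 + X0)


def no_cooperation_exists(R1: float, R2: float, omega: float,
                          n: int, alpha: float) -> bool:
    """Existence of the all-defect (C = 0) equilibrium.

    Requires ``R2 < 1 + omega * R1 * (1 - sqrt(n**alpha / R1))``; the
    state is additionally stable to small power perturbations whenever
    ``eps < 1``. Presumes ``R1 >= n**alpha`` so every defecting group
    makes nonzero effort.
    """
    na = n ** alpha
    if R1 < na:
        raise ValueError(
            f"no-cooperation condition assumes R1 >= n**alpha ({na}), "
            f"got R1 = {R1}")
    return R2 < 1.0 + omega * R1 * (1.0 - math.sqrt(na / R1))


def symmetric_coalition_effort(C: int, R1: float, R2: float, omega: float,
                               n: int, alpha: float, X0: float) -> float:
    """Per-group effort X_c* in a symmetric coalition of C groups.

    ``X_c* = X0 / (omega*C*R1 + 1) * (sqrt(R1*R2 / (C * n**alpha)) - 1)``,
    positive iff ``R1 * R2 > C * n**alpha`` (0 is returned otherwise: the
    equilibrium does not exist). Decreasing in n, omega, alpha, R1 and C;
    increasing in R2; independent of G.
    """
    if C < 1:
        raise ValueError(f"coalition size must be >= 1, got {C}")
    na = n ** alpha
    val = X0 / (omega * C * R1 + 1.0) * (
        math.sqrt(R1 * R2 / (C * na)) - 1.0)
    return max(0.0, val)


def no_defection_condition(C: int, R1: float, R2: float, omega: float,
                           n: int, alpha: float) -> bool:
    """No coalition member gains by unilaterally defecting.

    Holds iff ``R1`` is below a threshold increasing in ``R2``:
    ``R1 < n**alpha * (C*R2/4) * (1 + sqrt(1 + 4/(C^2 n**alpha omega)
    * (1 - 1/R2)))**2``. When ``R2 <= 1`` the inner square root can turn
    negative, in which case the condition is inapplicable and False is
    returned.
    """
    if R2 <= 0:
        raise ValueError(f"R2 must be > 0, got {R2}")
    na = n ** alpha
    inner = 1.0 + 4.0 / (C * C * na * omega) * (1.0 - 1.0 / R2)
    if inner < 0:
        return False
    threshold = na * (C * R2 / 4.0) * (1.0 + math.sqrt(inner)) ** 2
    return R1 < threshold


def eps_max_full_coalition(params: ModelParams) -> float:
    """Closed-form incumbency ceiling for the full-coalition equilibrium.

    With all G equal-size groups cooperating at the symmetric effort X_c*
    (C = G), the equilibrium is stable to small power perturbations iff
    ``eps < eps_max = A_c* / (A_c* + Q_G / G**2)``, where
    ``A_c* = n*pi0 - c*X_c*`` is each group's resource before the club
    good is divided and ``Q_G`` is the club good produced at the
    equilibrium (each group contributing ``P(X_c*)``).
    """
    sizes = set(params.group_sizes)
    if len(sizes) != 1:
        raise ValueError("eps_max closed form requires equal group sizes")
    n = sizes.pop()
    G = params.G
    Xc = symmetric_coalition_effort(G, params.R1, params.R2, params.omega,
                                    n, params.alpha, params.X0)
    if Xc <= 0:
        raise ValueError("full-coalition equilibrium absent: X_c* <= 0")
    A_c = n * params.pi0 - params.c * Xc
    Z_G = G * group_production(Xc, params.B1, params.X0)
    Q_G = coalition_production(Z_G, params.B2, params.Z0)
    return A_c / (A_c + Q_G / G ** 2)


def symmetric_coalition_state(params: ModelParams, C: int,
                              X_int: int) -> SocietyState:
    """Integer-valued symmetric state: C cooperating groups at effort X_int.

    The first ``C`` groups cooperate, each with its first ``X_int``
    members contributing; defecting groups (if any) play the isolated-
    group effort. Powers are equal.
    """
    sizes = set(params.group_sizes)
    if len(sizes) != 1:
        raise ValueError("symmetric state requires equal group sizes")
    n = sizes.pop()
    if not 0 <= X_int <= n:
        raise ValueError(f"effort {X_int} outside [0, {n}]")
    X_def = int(round(single_group_effort(params.R1, n, params.alpha,
                                          params.X0)))
    x = np.zeros(params.total_n, dtype=np.int8)
    theta = np.zeros(params.G, dtype=np.int8)
    for j in range(params.G):
        k = X_int if j < C else X_def
        x[params.offsets[j]:params.offsets[j] + k] = 1
        theta[j] = 1 if (j < C and X_int > 0) else 0
    f = np.full(params.G, 1.0 / params.G)
    return SocietyState(x=x, theta=theta, f=f)


def power_stability_probe(params: ModelParams, C: int, X_int: int,
                          delta: float = 1e-3, horizon: int = 2000) -> bool:
    """Numerically test power stability of a symmetric candidate equilibrium.

    Strategies are frozen at the symmetric state; one cooperating group's
    power is perturbed by ``+delta`` (renormalized) and the power map
    (payoffs -> effective efforts -> contest) is iterated ``horizon``
    times. Stable iff the maximum deviation from the symmetric powers
    shrinks below ``delta / 10``.
    """
    if C < 1:
        raise ValueError("probe requires a coalition (C >= 1)")
    if delta == 0:
        return True
    state = symmetric_coalition_state(params, C, X_int)
    if state.theta.sum() != C:
        raise ValueError("candidate state is not a coalition equilibrium "
                         "(membership rule removed a group)")
    f_sym = state.f.copy()
    f = f_sym.copy()
    f[0] += delta
    f /= f.sum()
    state.f = f
    for _ in range(horizon):
        rec = play_games(state, params)
        state.f = rec.f_next
        dev = np.abs(state.f - f_sym).max()
        if dev < delta / 10.0:
            return True
    return False


def eps_max_numeric(params: ModelParams, C: int, X_int: int,
                    tol: float = 1e-3, **probe_kwargs) -> float:
    """Largest stable incumbency value by bisection on the probe.

    Searches ``eps`` in [0, 1] for the boundary between probe-stable and
    probe-unstable, to absolute tolerance ``tol``. Returns 1.0 when even
    ``eps = 1`` is stable and 0.0 when even ``eps = 0`` is not.
    """
    def stable(eps: float) -> bool:
        return power_stability_probe(params.with_(epsilon=eps), C, X_int,
                                     **probe_kwargs)
    lo, hi = 0.0, 1.0
    if stable(hi):
        return 1.0
    if not stable(lo):
        return 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stable(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def stability_region_scan(params: ModelParams, R1_grid, second_axis: str,
                          second_grid, C: int | None = None) -> pd.DataFrame:
    """Existence/stability verdicts over a (R1, eps) or (R1, R2) grid.

    ``second_axis`` is "epsilon" or "R2". For each grid point the
    no-cooperation condition, the symmetric-coalition effort and the
    no-defection condition are evaluated; for C = G the closed-form
    ``eps_max`` supplies the stability verdict, otherwise stability is
    left to the numerical probe (not run here — it is per-point expensive
    and exposed separately).
    """
    if second_axis not in ("epsilon", "R2"):
        raise ValueError("second_axis must be 'epsilon' or 'R2'")
    sizes = set(params.group_sizes)
    if len(sizes) != 1:
        raise ValueError("region scan requires equal group sizes")
    n = sizes.pop()
    if C is None:
        C = params.G
    rows = []
    for R1 in R1_grid:
        B1 = R1 * params.c * params.X0
        for val in second_grid:
            if second_axis == "epsilon":
                p = params.with_(B1=B1, epsilon=float(val))
            else:
                p = params.with_(B1=B1, B2=float(val) * params.Z0)
            Xc = symmetric_coalition_effort(C, p.R1, p.R2, p.omega, n,
                                            p.alpha, p.X0)
            exists = Xc > 0 and no_defection_condition(
                C, p.R1, p.R2, p.omega, n, p.alpha)
            row = {"R1": float(R1), second_axis: float(val), "C": C,
                   "X_c_star": Xc, "exists": bool(exists)}
            if exists and C == p.G:
                row["eps_max"] = eps_max_full_coalition(p)
                row["stable"] = p.epsilon < row["eps_max"]
            else:
                row["eps_max"] = float("nan")
                row["stable"] = None
            if p.R1 >= n ** p.alpha:
                row["no_coop_exists"] = no_cooperation_exists(
                    p.R1, p.R2, p.omega, n, p.alpha)
            else:
                row["no_coop_exists"] = None
            rows.append(row)
    return pd.DataFrame(rows)
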