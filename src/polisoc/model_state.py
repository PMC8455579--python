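"""Parameterization and mutable state of the group-structured society model.

A society consists of ``G`` groups of sizes ``n_j``. Individuals hold binary
contribution strategies ``x_ij`` for the within-group public-goods game,
groups hold binary cooperation statuses ``theta_j`` for the between-group
club-goods game, and each group carries a political power ``f_j`` with
``sum_j f_j = 1``. All model constants are time-independent and validated at
construction time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "SocietyState",
    "StepRecord",
    "ParamError",
    "StateError",
    "make_params",
    "params_from_json",
    "validate_state",
    "POWER_TOL",
]

#: Absolute tolerance on the power-sum invariant sum_j f_j = 1. The Tullock
#: update renormalizes exactly up to rounding, so violations beyond this are
#: treated as errors, never silently fixed.
POWER_TOL = 1e-12


class ParamError(ValueError):
    """A model parameter violates its documented bound."""


class StateError(ValueError):
    """A society state is malformed or violates a state invariant."""


_REQUIRED_FIELDS = (
    "G", "B1", "X0", "B2", "Z0", "c", "pi0",
    "alpha", "epsilon", "mu1", "mu2", "lam",
)
_ALL_FIELDS = _REQUIRED_FIELDS + ("group_sizes", "n")


@dataclass(frozen=True)
class ModelParams:
    """Time-independent constants of the model.

    Parameters
    ----------
    G : int
        Number of groups (>= 1).
    group_sizes : tuple of int
        Group sizes ``n_j`` (each >= 1), length ``G``.
    B1 : float
        Maximum benefit of within-group cooperation (> 0).
    X0 : float
        Within-group half-effort: group production reaches ``B1/2`` at
        combined effort ``X0`` (> 0).
    B2 : float
        Maximum benefit of between-group cooperation (>= 0).
    Z0 : float
        Between-group half-effort (> 0).
    c : float
        Individual contribution cost, ``0 < c <= pi0``.
    pi0 : float
        Baseline individual endowment (> 0).
    alpha : float
        Rivalrousness of the goods in [0, 1]: each individual receives a
        ``1/n_j**alpha`` share of its group's resource. ``alpha = 1`` is
        fully rival, ``alpha = 0`` pure public.
    epsilon : float
        Incumbency parameter in [0, 1]: strength with which current power
        amplifies a group's effective political effort. Small values model
        strong checks-and-balances.
    mu1, mu2 : float
        Per-step revision probabilities for individuals and groups, in
        [0, 1].
    lam : float
        Logit decision precision, in [0, inf]; ``math.inf`` selects exact
        (errorless) best response.
    """

    G: int
    group_sizes: tuple[int, ...]
    B1: float
    X0: float
    B2: float
    Z0: float
    c: float
    pi0: float
    alpha: float
    epsilon: float
    mu1: float
    mu2: float
    lam: float

    def __post_init__(self) -> None:
        if not isinstance(self.G, (int, np.integer)) or self.G < 1:
            raise ParamError(f"G must be an integer >= 1, got {self.G!r}")
        sizes = tuple(int(n) for n in self.group_sizes)
        if len(sizes) != self.G:
            raise ParamError(
                f"group_sizes has length {len(sizes)}, expected G={self.G}")
        if any(n < 1 for n in sizes):
            raise ParamError(f"group sizes must be integers >= 1, got {sizes}")
        object.__setattr__(self, "group_sizes", sizes)
        _check_positive("B1", self.B1)
        _check_positive("X0", self.X0)
        if self.B2 < 0:
            raise ParamError(f"B2 must be >= 0, got {self.B2}")
        _check_positive("Z0", self.Z0)
        _check_positive("pi0", self.pi0)
        if not 0 < self.c <= self.pi0:
            raise ParamError(
                f"c must satisfy 0 < c <= pi0 (= {self.pi0}), got {self.c}")
        _check_unit("alpha", self.alpha)
        _check_unit("epsilon", self.epsilon)
        _check_unit("mu1", self.mu1)
        _check_unit("mu2", self.mu2)
        if self.lam < 0:
            raise ParamError(f"lam must be >= 0 (inf allowed), got {self.lam}")

    # -- derived quantities (pure functions of the fields) ----------------

    @property
    def R1(self) -> float:
        """Benefit-to-cost ratio of the within-group game, B1/(c*X0)."""
        return self.B1 / (self.c * self.X0)

    @property
    def R2(self) -> float:
        """Benefit-to-cost ratio of the between-group game, B2/Z0."""
        return self.B2 / self.Z0

    @property
    def omega(self) -> float:
        """Cost ratio of the within- vs between-group games, c*X0/Z0."""
        return self.c * self.X0 / self.Z0

    @property
    def Pi0(self) -> np.ndarray:
        """Per-group baseline resource n_j * pi0."""
        return np.asarray(self.group_sizes, float) * self.pi0

    @property
    def b1(self) -> np.ndarray:
        """Per-capita maximum within-group benefit B1 / n_j**alpha."""
        return self.B1 / self.n_alpha

    @property
    def b2(self) -> float:
        """Per-capita maximum between-group benefit B2 / sum_j n_j**alpha."""
        return self.B2 / float(self.n_alpha.sum())

    @property
    def n_alpha(self) -> np.ndarray:
        """Per-group rivalry divisor n_j**alpha."""
        return np.asarray(self.group_sizes, float) ** self.alpha

    @property
    def total_n(self) -> int:
        return sum(self.group_sizes)

    @property
    def offsets(self) -> np.ndarray:
        """Start index of each group's members in a flat individual array."""
        return np.concatenate(([0], np.cumsum(self.group_sizes)[:-1]))

    def with_(self, **changes) -> "ModelParams":
        """Return a validated copy with the given fields replaced."""
        return replace(self, **changes)


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ParamError(f"{name} must be > 0, got {value}")


def _check_unit(name: str, value: float) -> None:
    if not 0 <= value <= 1:
        raise ParamError(f"{name} must lie in [0, 1], got {value}")


def make_params(raw: Mapping) -> ModelParams:
    """Build validated :class:`ModelParams` from a mapping.

    ``group_sizes`` may be given explicitly (list of length G) or as a
    single scalar ``n`` broadcast to all ``G`` groups. Unknown keys are an
    error so that typos in sweep configurations fail loudly.
    """
    unknown = set(raw) - set(_ALL_FIELDS)
    if unknown:
        raise ParamError(f"unknown parameter keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED_FIELDS if k not in raw]
    if missing:
        raise ParamError(f"missing required parameter keys: {missing}")
    d = dict(raw)
    G = d["G"]
    if "group_sizes" in d and "n" in d:
        raise ParamError("give either 'group_sizes' or 'n', not both")
    if "group_sizes" in d:
        sizes = tuple(int(v) for v in d.pop("group_sizes"))
    elif "n" in d:
        sizes = (int(d.pop("n")),) * int(G)
    else:
        raise ParamError("one of 'group_sizes' or 'n' is required")
    lam = d["lam"]
    if isinstance(lam, str):
        if lam.lower() in ("inf", "infinity"):
            lam = math.inf
        else:
            raise ParamError(f"lam must be a number or 'inf', got {lam!r}")
    return ModelParams(
        G=int(G), group_sizes=sizes,
        B1=float(d["B1"]), X0=float(d["X0"]),
        B2=float(d["B2"]), Z0=float(d["Z0"]),
        c=float(d["c"]), pi0=float(d["pi0"]),
        alpha=float(d["alpha"]), epsilon=float(d["epsilon"]),
        mu1=float(d["mu1"]), mu2=float(d["mu2"]), lam=float(lam),
    )


def params_from_json(path) -> ModelParams:
    """Load :class:`ModelParams` from a JSON document on disk."""
    with open(path) as fh:
        return make_params(json.load(fh))


@dataclass
class SocietyState:
    """Mutable society state at one time step.

    Attributes
    ----------
    x : ndarray of int8, length sum(n_j)
        Flat per-individual contributions, groups concatenated in order.
    theta : ndarray of int8, length G
        Per-group cooperation status in the between-group game.
    f : ndarray of float, length G
        Political power vector, summing to 1.
    """

    x: np.ndarray
    theta: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)
        self.theta = np.asarray(self.theta, dtype=np.int8)
        self.f = np.asarray(self.f, dtype=float)

    def group_efforts(self, params: ModelParams) -> np.ndarray:
        """Per-group combined effort X_j = sum_i x_ij."""
        return np.add.reduceat(self.x.astype(np.int64), params.offsets)

    def copy(self) -> "SocietyState":
        return SocietyState(self.x.copy(), self.theta.copy(), self.f.copy())


@dataclass
class StepRecord:
    """Realized quantities of one simulation step (after strategy revision).

    ``theta`` and ``f`` are the strategies/powers at which the games were
    played; ``f_next`` is the power vector produced by the political contest.
    """

    t: int
    X: np.ndarray
    P: np.ndarray
    C: int
    Z: float
    Q: float
    v: np.ndarray
    Pi: np.ndarray
    y: np.ndarray
    theta: np.ndarray = field(default=None)  # type: ignore[assignment]
    f: np.ndarray = field(default=None)  # type: ignore[assignment]
    f_next: np.ndarray = field(default=None)  # type: ignore[assignment]


def validate_state(state: SocietyState, params: ModelParams) -> list[str]:
    """Check all state invariants; return a list of violation messages.

    An empty list means the state is valid. Shape mismatches raise
    :class:`StateError` (the invariants are not even well-posed then).
    """
    if state.x.shape != (params.total_n,):
        raise StateError(
            f"x has shape {state.x.shape}, expected ({params.total_n},)")
    if state.theta.shape != (params.G,):
        raise StateError(
            f"theta has shape {state.theta.shape}, expected ({params.G},)")
    if state.f.shape != (params.G,):
        raise StateError(
            f"f has shape {state.f.shape}, expected ({params.G},)")

    violations: list[str] = []
    if not np.isin(state.x, (0, 1)).all():
        violations.append("x contains values outside {0, 1}")
    if not np.isin(state.theta, (0, 1)).all():
        violations.append("theta contains values outside {0, 1}")
    if (state.f < 0).any() or (state.f > 1).any():
        bad = np.where((state.f < 0) | (state.f > 1))[0]
        violations.append(f"power outside [0, 1] at groups {bad.tolist()}")
    if abs(state.f.sum() - 1.0) > POWER_TOL:
        violations.append(f"power sum != 1 (got {state.f.sum()!r})")
    X = state.group_efforts(params)
    bad = np.where((X == 0) & (state.theta == 1))[0]
    for j in bad:
        violations.append(f"elite rule violated at group {j}: theta=1, X=0")
    return violations
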