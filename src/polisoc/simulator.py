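"""Time-stepping engine, initialization, and ensemble runner.

A step proceeds as: (1) individuals revise contributions, (2) groups revise
cooperation statuses (with the membership rule applied), (3) the economic
games are played on the revised strategies, (4) the political contest
updates powers. Strategies are thus myopic responses to the previous
step's realized state, and payoffs are realized after revision.

Initial conditions follow the model's standard protocol: powers drawn from
a broken-stick partition of [0, 1] when groups share one size (equal powers
otherwise), and every individual and group cooperating independently with
probability 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decisions import enforce_membership_rule, revise_groups, revise_individuals
from .games import play_games
from .model_state import ModelParams, SocietyState, StepRecord

__all__ = [
    "Trajectory",
    "init_power_broken_stick",
    "init_state",
    "step",
    "run",
    "run_ensemble",
    "trajectory_frame",
]


@dataclass
class Trajectory:
    """A full simulation run: parameters, seed, per-step records and states.

    ``records[k]`` was produced by the revised strategies of step ``k+1``;
    ``states[k]`` is the state after that step (same strategies, powers
    advanced by the contest).
    """

    params: ModelParams
    seed: object
    records: list[StepRecord] = field(default_factory=list)
    states: list[SocietyState] = field(default_factory=list)
    initial_state: SocietyState | None = None

    @property
    def T(self) -> int:
        return len(self.records)


def init_power_broken_stick(G: int, rng: np.random.Generator) -> np.ndarray:
    """Initial powers from a broken-stick partition of the unit interval.

    G - 1 independent uniform cut points split [0, 1]; the segment lengths,
    taken in position order, are the powers. Each segment has expectation
    1/G by symmetry.
    """
    if G == 1:
        return np.array([1.0])
    cuts = np.sort(rng.random(G - 1))
    return np.diff(np.concatenate(([0.0], cuts, [1.0])))


def init_state(params: ModelParams, rng: np.random.Generator,
               equal_power: bool = False) -> SocietyState:
    """Random initial state under the standard protocol.

    Powers come from the broken stick when all groups share one size and
    ``equal_power`` is not requested; societies with unequal group sizes
    always start at equal power. Contributions and statuses are fair coin
    flips, with the membership rule applied afterwards.
    """
    sizes_equal = len(set(params.group_sizes)) == 1
    if sizes_equal and not equal_power:
        f = init_power_broken_stick(params.G, rng)
    else:
        f = np.full(params.G, 1.0 / params.G)
    x = (rng.random(params.total_n) < 0.5).astype(np.int8)
    theta = (rng.random(params.G) < 0.5).astype(np.int8)
    state = SocietyState(x=x, theta=theta, f=f)
    enforce_membership_rule(state, params)
    return state


def step(state: SocietyState, params: ModelParams,
         rng: np.random.Generator, t: int = 0
         ) -> tuple[SocietyState, StepRecord]:
    """Advance the society one time step; returns (new state, record)."""
    new_x = revise_individuals(state, params, rng)
    mid = SocietyState(x=new_x, theta=state.theta.copy(), f=state.f.copy())
    new_theta = revise_groups(mid, params, rng)
    played = SocietyState(x=new_x, theta=new_theta, f=state.f.copy())
    record = play_games(played, params, t=t)
    new_state = SocietyState(x=new_x.copy(), theta=new_theta.copy(),
                             f=record.f_next.copy())
    return new_state, record


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def run(params: ModelParams, T: int, seed,
        initial_state: SocietyState | None = None,
        store_states: bool = True) -> Trajectory:
    """Simulate ``T`` steps from a fresh (or supplied) initial state.

    The trajectory is fully determined by ``(params, T, seed)`` (plus the
    initial state if given). ``seed`` may be an int, a ``SeedSequence`` or
    a ``Generator``. Per-step states are stored compactly unless
    ``store_states`` is off; records are always kept.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    rng = _as_rng(seed)
    state = init_state(params, rng) if initial_state is None \
        else initial_state.copy()
    traj = Trajectory(params=params, seed=seed, initial_state=state.copy())
    for t in range(1, T + 1):
        state, record = step(state, params, rng, t=t)
        traj.records.append(record)
        if store_states:
            traj.states.append(state.copy())
    if not store_states:
        traj.states.append(state.copy())  # keep the final state regardless
    return traj


def run_ensemble(params: ModelParams, T: int, n_runs: int, base_seed,
                 window: int | None = None, store_states: bool = True):
    """Independent seeded runs, each summarized over its final window.

    One master ``SeedSequence`` spawns a child stream per run index, so
    runs are statistically independent and the whole ensemble reproducible
    from ``base_seed``. Returns a list of ``RunSummary``.
    """
    from .metrics import summarize_window

    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    if window is None:
        window = max(1, T // 4)
    master = base_seed if isinstance(base_seed, np.random.SeedSequence) \
        else np.random.SeedSequence(base_seed)
    summaries = []
    for k, child in enumerate(master.spawn(n_runs)):
        traj = run(params, T, np.random.default_rng(child),
                   store_states=store_states)
        summary = summarize_window(traj, window)
        summary.seed = f"{master.entropy}:{k}"
        summaries.append(summary)
    return summaries


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy per-step table: one row per (t, group).

    Columns: t, group, X, theta, f, Pi, C, Q (theta/f as played; C and Q
    repeated across groups of a step).
    """
    rows = []
    for rec in traj.records:
        for j in range(traj.params.G):
            rows.append({
                "t": rec.t, "group": j, "X": int(rec.X[j]),
                "theta": int(rec.theta[j]), "f": float(rec.f_next[j]),
                "Pi": float(rec.Pi[j]), "C": rec.C, "Q": rec.Q,
            })
    return pd.DataFrame(rows)
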