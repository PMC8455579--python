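"""Experiment drivers: configuration, parameter sweeps, and fixtures.

Sweep protocols mirror the model's standard numerical experiments (many
seeded runs per parameter combination, statistics over the trailing
window), at a configurable scale. Defaults here are deliberately small
(n_runs=10, T=1000, window=250); production scale (100-200 runs of 4000
steps, window 1000) is a config change.

Configs may specify the benefit parameters either raw (``B1``, ``B2``) or
per capita (``b1 = B1 / n**alpha``, requires equal group sizes, and
``b2 = B2 / sum_j n_j**alpha``); per-capita values are converted and the
conversion is logged so it can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .model_state import ModelParams, ParamError, SocietyState, make_params
from .metrics import aggregate_summaries, summaries_frame
from .simulator import run_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "SweepConfig",
    "params_from_config",
    "run_sweep",
    "make_fixture",
    "FIXTURES",
]

_SWEEP_DEFAULTS = dict(T=1000, window=250, n_runs=10)


def params_from_config(config: dict) -> ModelParams:
    """Build ModelParams from a config dict, converting per-capita benefits.

    ``b1``/``b2`` (if present) replace ``B1``/``B2`` after conversion;
    giving both the raw and per-capita form of the same benefit is an
    error.
    """
    d = dict(config)
    if "b1" in d or "b2" in d:
        if "n" in d:
            sizes = [int(d["n"])] * int(d["G"])
        else:
            sizes = [int(v) for v in d.get("group_sizes", [])]
        if not sizes:
            raise ParamError("per-capita benefits need group sizes")
        alpha = float(d["alpha"])
        if "b1" in d:
            if "B1" in d:
                raise ParamError("give either b1 or B1, not both")
            if len(set(sizes)) != 1:
                raise ParamError("b1 -> B1 conversion requires equal sizes")
            b1 = float(d.pop("b1"))
            d["B1"] = b1 * sizes[0] ** alpha
            logger.info("converted b1=%g to B1=%g (n=%d, alpha=%g)",
                        b1, d["B1"], sizes[0], alpha)
        if "b2" in d:
            if "B2" in d:
                raise ParamError("give either b2 or B2, not both")
            b2 = float(d.pop("b2"))
            total = sum(n ** alpha for n in sizes)
            d["B2"] = b2 * total
            logger.info("converted b2=%g to B2=%g (sum n^alpha=%g)",
                        b2, d["B2"], total)
    return make_params(d)


@dataclass
class SweepConfig:
    """A factorial sweep: base parameters x swept axes x seeded runs."""

    base: dict
    axes: dict[str, list] = field(default_factory=dict)
    T: int = _SWEEP_DEFAULTS["T"]
    window: int = _SWEEP_DEFAULTS["window"]
    n_runs: int = _SWEEP_DEFAULTS["n_runs"]
    base_seed: int = 0

    def __post_init__(self) -> None:
        base_params = params_from_config(self.base)  # validates the base
        for name, values in self.axes.items():
            if not hasattr(base_params, name):
                raise ParamError(f"swept name {name!r} is not a model "
                                 "parameter field")
            if not values:
                raise ParamError(f"swept axis {name!r} has no values")
            for v in values:
                base_params.with_(**{name: v})  # bounds-check every value
        if self.T < 1 or self.window < 1 or self.window > self.T:
            raise ParamError("need 1 <= window <= T")
        if self.n_runs < 1:
            raise ParamError("n_runs must be >= 1")


def run_sweep(config: SweepConfig, out_dir: str | Path | None = None
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the full factorial sweep; returns (tidy runs, aggregates).

    When ``out_dir`` is given, results stream to ``runs.csv`` and
    ``aggregate.csv`` there, and combinations already present in an
    existing ``runs.csv`` are skipped, so an interrupted sweep resumes
    where it stopped.
    """
    base_params = params_from_config(config.base)
    names = list(config.axes)
    combos = list(product(*(config.axes[n] for n in names))) or [()]

    runs_path = agg_path = None
    done: set[tuple] = set()
    frames: list[pd.DataFrame] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        runs_path = out_dir / "runs.csv"
        agg_path = out_dir / "aggregate.csv"
        if runs_path.exists():
            prev = pd.read_csv(runs_path)
            frames.append(prev)
            if names and len(prev):
                done = {tuple(row) for row in
                        prev[names].drop_duplicates().itertuples(index=False)}

    # combination index keys the per-combination seed stream, so resuming
    # reproduces exactly what a fresh full sweep would have produced
    master = np.random.SeedSequence(config.base_seed)
    children = master.spawn(len(combos))
    for idx, combo in enumerate(combos):
        if tuple(combo) in done:
            logger.info("skipping completed combination %s", dict(zip(names,
                                                                      combo)))
            continue
        params = base_params.with_(**dict(zip(names, combo)))
        summaries = run_ensemble(params, config.T, config.n_runs,
                                 children[idx], window=config.window)
        frame = summaries_frame(summaries)
        for name, value in zip(names, combo):
            frame.insert(0, name, value)
        frames.append(frame)
        if runs_path is not None:
            pd.concat(frames, ignore_index=True).to_csv(runs_path,
                                                        index=False)
    tidy = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    agg = aggregate_summaries(tidy, by=names or None) if len(tidy) \
        else pd.DataFrame()
    if agg_path is not None:
        agg.to_csv(agg_path, index=False)
    return tidy, agg


# ---------------------------------------------------------------------------
# fixture catalogue: deterministic micro-societies for tests and examples

_COMMON = dict(c=1.0, pi0=1.0, X0=5.0, Z0=50.0,
               mu1=0.25, mu2=0.25, lam=float("inf"))


def _two_symmetric_groups():
    params = make_params(dict(G=2, n=4, B1=40.0, B2=60.0,
                              alpha=1.0, epsilon=0.2, **_COMMON))
    x = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=np.int8)
    theta = np.array([1, 1], dtype=np.int8)
    f = np.array([0.5, 0.5])
    return params, SocietyState(x=x, theta=theta, f=f)


def _lone_cooperator():
    params = make_params(dict(G=3, n=3, B1=30.0, B2=90.0,
                              alpha=1.0, epsilon=0.1, **_COMMON))
    x = np.array([1, 1, 0, 1, 0, 0, 1, 0, 0], dtype=np.int8)
    theta = np.array([1, 0, 0], dtype=np.int8)
    f = np.array([0.5, 0.3, 0.2])
    return params, SocietyState(x=x, theta=theta, f=f)


def _four_group_turnover():
    # four equal groups in the regime with persistent strategy/power cycling
    # (per-capita benefits b1=10, b2=26)
    params = params_from_config(dict(G=4, n=10, b1=10.0, b2=26.0,
                                     alpha=1.0, epsilon=0.1, **_COMMON))
    x = np.zeros(40, dtype=np.int8)
    x[::2] = 1
    theta = np.ones(4, dtype=np.int8)
    f = np.full(4, 0.25)
    return params, SocietyState(x=x, theta=theta, f=f)


def _olson():
    # four groups of 5/10/15/20 at equal power: the group-size paradox setup
    params = make_params(dict(G=4, group_sizes=[5, 10, 15, 20], B1=100.0,
                              B2=50.0, alpha=1.0, epsilon=0.5, **_COMMON))
    x = np.zeros(50, dtype=np.int8)
    for j, k in enumerate((3, 2, 1, 1)):
        x[params.offsets[j]:params.offsets[j] + k] = 1
    theta = np.zeros(4, dtype=np.int8)
    f = np.full(4, 0.25)
    return params, SocietyState(x=x, theta=theta, f=f)


def _focal_n(n: int = 22):
    # three groups of 5/10/15 plus a focal group whose size is the lever
    params = make_params(dict(G=4, group_sizes=[5, 10, 15, int(n)],
                              B1=100.0, B2=1500.0, alpha=1.0, epsilon=0.3,
                              c=1.0, pi0=1.0, X0=5.0, Z0=300.0,
                              mu1=0.25, mu2=0.25, lam=float("inf")))
    x = np.zeros(params.total_n, dtype=np.int8)
    for j in range(4):
        x[params.offsets[j]] = 1
    theta = np.ones(4, dtype=np.int8)
    f = np.full(4, 0.25)
    return params, SocietyState(x=x, theta=theta, f=f)


FIXTURES = {
    "two-symmetric-groups": _two_symmetric_groups,
    "lone-cooperator": _lone_cooperator,
    "four-group-turnover": _four_group_turnover,
    "olson": _olson,
    "focal-n": _focal_n,
}


def make_fixture(name: str) -> tuple[ModelParams, SocietyState]:
    """Deterministic micro-society by catalogue name.

    Raises ``KeyError`` listing the catalogue for unknown names.
    """
    try:
        factory = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{sorted(FIXTURES)}") from None
    return factory()
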