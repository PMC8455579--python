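"""Summary statistics and regime classification for simulation output.

The headline statistics of a run are the coalition size ``C``, the Gini
index ``I`` of power inequality among cooperating groups, and the standard
deviation ``sigma`` of cooperating-group efforts, averaged over the last
part of the run. Runs are classified as equilibrium (strategies frozen,
powers settled) or non-equilibrium, and equilibrium coalitions by their
power structure (equal elites vs dominant/subordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_state import StepRecord
from .simulator import Trajectory

__all__ = [
    "RunSummary",
    "gini",
    "coalition_stats",
    "summarize_window",
    "classify_regime",
    "classify_elite_structure",
    "summaries_frame",
    "aggregate_summaries",
]

#: Power-settledness tolerance for the equilibrium classifier: within the
#: window every power must stay within f_tol of its window mean. Power
#: converges geometrically once strategies freeze, so this is generous.
DEFAULT_F_TOL = 1e-6
#: Gap width separating power classes when clustering cooperating groups'
#: mean powers into equal vs dominant/subordinate structures.
DEFAULT_POWER_TOL = 1e-3


@dataclass
class RunSummary:
    """Window-averaged statistics of a single run."""

    mean_C: float
    gini_I: float          # NaN when no window step had >= 1 cooperator
    sd_sigma: float        # ditto
    mean_X: np.ndarray     # per-group mean effort
    mean_theta: np.ndarray
    mean_f: np.ndarray
    regime: str            # "equilibrium" | "non-equilibrium"
    elite_structure: str | None = None
    window: int = 0
    seed: object = None


def gini(values) -> float:
    """Gini index: half of the relative mean absolute difference.

    ``I = sum_ij |v_i - v_j| / (2 m^2 mean(v))`` for a nonnegative vector
    of length m. Scale- and permutation-invariant; 0 for a constant
    vector; at most (m-1)/m. An all-zero vector has no defined inequality
    and returns NaN.
    """
    v = np.asarray(values, float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("gini requires a non-empty 1-D vector")
    if (v < 0).any():
        raise ValueError("gini requires nonnegative values")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    m = v.size
    mad = np.abs(v[:, None] - v[None, :]).sum()
    return float(mad / (2 * m * m * mean))


def coalition_stats(record: StepRecord) -> tuple[int, float, float]:
    """(C, Gini of cooperators' powers, population SD of their efforts).

    Restricted to groups with theta = 1. With no cooperators the
    inequality statistics are undefined (NaN); a singleton coalition has
    both equal to 0.
    """
    coop = record.theta == 1
    C = int(coop.sum())
    if C == 0:
        return 0, float("nan"), float("nan")
    f_coop = record.f[coop]
    X_coop = record.X[coop].astype(float)
    g = gini(f_coop) if f_coop.sum() > 0 else 0.0
    return C, g, float(X_coop.std())  # population SD: ddof=0


def summarize_window(traj: Trajectory, window: int) -> RunSummary:
    """Average per-step statistics over the last ``window`` steps.

    Steps with an empty coalition are excluded from the Gini/SD averages
    (inequality among cooperators is undefined there), never imputed as 0.
    """
    T = traj.T
    if window > T:
        raise ValueError(f"window {window} longer than trajectory of {T} steps")
    recs = traj.records[T - window:]
    per_step = [coalition_stats(r) for r in recs]
    C_vals = np.array([s[0] for s in per_step], float)
    g_vals = np.array([s[1] for s in per_step], float)
    sd_vals = np.array([s[2] for s in per_step], float)
    mean_C = float(C_vals.mean())
    gini_I = float(np.nanmean(g_vals)) if not np.isnan(g_vals).all() \
        else float("nan")
    sd_sigma = float(np.nanmean(sd_vals)) if not np.isnan(sd_vals).all() \
        else float("nan")
    mean_X = np.mean([r.X for r in recs], axis=0)
    mean_theta = np.mean([r.theta for r in recs], axis=0)
    mean_f = np.mean([r.f_next for r in recs], axis=0)
    regime = classify_regime(traj, window)
    summary = RunSummary(mean_C=mean_C, gini_I=gini_I, sd_sigma=sd_sigma,
                         mean_X=mean_X, mean_theta=mean_theta, mean_f=mean_f,
                         regime=regime, window=window)
    if regime == "equilibrium":
        summary.elite_structure = classify_elite_structure(summary)
    return summary


def classify_regime(traj: Trajectory, window: int,
                    f_tol: float = DEFAULT_F_TOL) -> str:
    """Equilibrium iff strategies are frozen and powers settled in-window.

    Every individual contribution and every group status must be constant
    over the last ``window`` steps, and each power must stay within
    ``f_tol`` of its window mean. Anything else is non-equilibrium.
    """
    T = traj.T
    if window > T:
        raise ValueError(f"window {window} longer than trajectory of {T} steps")
    if len(traj.states) < window:
        raise ValueError("regime classification needs stored per-step states")
    states = traj.states[len(traj.states) - window:]
    x0 = states[0].x
    th0 = states[0].theta
    for s in states[1:]:
        if not np.array_equal(s.x, x0) or not np.array_equal(s.theta, th0):
            return "non-equilibrium"
    fs = np.array([s.f for s in states])
    if np.abs(fs - fs.mean(axis=0)).max() >= f_tol:
        return "non-equilibrium"
    return "equilibrium"


def classify_elite_structure(summary: RunSummary,
                             power_tol: float = DEFAULT_POWER_TOL) -> str:
    """Power structure of an equilibrium coalition.

    Cooperating groups' mean powers are clustered 1-D with gap width
    ``power_tol``: no cooperators -> "none"; one power class -> "equal";
    two classes -> "dominant-subordinate". More than two classes
    contradicts the model's equilibrium taxonomy (cooperating groups come
    in at most two power classes) and raises — it signals an upstream
    misclassification.
    """
    if summary.regime != "equilibrium":
        raise ValueError("elite structure is defined only at equilibrium")
    coop = summary.mean_theta > 0.5
    if not coop.any():
        return "none"
    powers = np.sort(summary.mean_f[coop])
    gaps = np.diff(powers)
    n_clusters = 1 + int((gaps > power_tol).sum())
    if n_clusters == 1:
        return "equal"
    if n_clusters == 2:
        return "dominant-subordinate"
    raise ValueError(
        f"{n_clusters} power classes among cooperating groups: violates the "
        "equilibrium taxonomy (at most dominant + subordinate); the run was "
        "probably misclassified as equilibrium")


def summaries_frame(summaries) -> pd.DataFrame:
    """Tidy table of ensemble results: one row per run."""
    rows = []
    for k, s in enumerate(summaries):
        rows.append({
            "run": k, "seed": str(s.seed), "mean_C": s.mean_C,
            "gini_I": s.gini_I, "sd_sigma": s.sd_sigma,
            "regime": s.regime, "elite_structure": s.elite_structure,
            **{f"mean_X_{j}": s.mean_X[j] for j in range(len(s.mean_X))},
            **{f"mean_theta_{j}": s.mean_theta[j]
               for j in range(len(s.mean_theta))},
            **{f"mean_f_{j}": s.mean_f[j] for j in range(len(s.mean_f))},
        })
    return pd.DataFrame(rows)


def aggregate_summaries(frame: pd.DataFrame,
                        by: list[str] | None = None) -> pd.DataFrame:
    """Mean and 95% normal CI half-width (1.96 SE) of the scalar statistics.

    ``by`` columns (e.g. swept parameters) group the aggregation; without
    them the whole frame is one cell.
    """
    scalars = ["mean_C", "gini_I", "sd_sigma"]
    def agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for col in scalars:
            vals = g[col].dropna().to_numpy()
            if vals.size:
                out[f"{col}_mean"] = vals.mean()
                se = vals.std(ddof=1) / np.sqrt(vals.size) \
                    if vals.size > 1 else 0.0
                out[f"{col}_ci95"] = 1.96 * se
            else:
                out[f"{col}_mean"] = np.nan
                out[f"{col}_ci95"] = np.nan
        out["n_runs"] = len(g)
        return pd.Series(out)
    if by:
        return frame.groupby(by, as_index=False).apply(agg,
                                                       include_groups=False)
    return agg(frame).to_frame().T
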