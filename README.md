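# polisoc

An agent-based model of cooperation, power, and inequality in a
group-structured society, for researchers in social evolution, cultural
evolution, and the political economy of collective action.

A society of `G` groups (sizes `n_j`, political powers `f_j`,
`Σ f_j = 1`) plays three nested games each time step:

- **Within groups** a nonlinear public-goods game: binary contributions
  `x_ij` at cost `c` produce `P_j = B1·X_j/(X_j + X0)` with
  `X_j = Σ_i x_ij`.
- **Between groups** a club-goods game: cooperating groups
  (`θ_j = 1`, the "elites") pool their production `Z` into
  `Q = B2·Z/(Z + Z0)`, divided in proportion to power
  (`v_j = f_j / Σ_{coalition} f_k`); defectors keep their own `P_j`.
  Individuals receive `1/n_j^α` shares (`α` = rivalrousness).
- **A Tullock contest for power**: effective effort
  `y_j = Π_j(1 − ε + ε f_j)` yields next-step power `f'_j = y_j/Σ y_k`.
  The incumbency parameter `ε` measures how much current power bends the
  contest; small `ε` models strong checks-and-balances.

Individuals and groups revise strategies by myopic best response with
logit errors (precision `λ`, revision probabilities `μ1`, `μ2`),
synchronously, against the pre-revision state. The package also provides
the closed-form equilibrium approximations (single-group effort,
symmetric coalition effort, existence and incumbency-stability
conditions), summary statistics (coalition size `C`, power Gini `I`,
effort dispersion `σ`, regime and elite-structure classification), a
numerical power-stability probe, and experiment drivers with a CLI.
See `docs/methods.md` for the full model description and the numerical
conventions.

## Worked example

Eight groups of ten, per-capita benefits `b1 = 20`, `b2 = 10`, rival
goods, moderate incumbency `ε = 0.2`:

```python
from polisoc import params_from_config, run, summarize_window

params = params_from_config({
    "G": 8, "n": 10, "b1": 20.0, "b2": 10.0, "alpha": 1.0,
    "epsilon": 0.2, "c": 1.0, "pi0": 1.0, "X0": 5.0, "Z0": 50.0,
    "mu1": 0.25, "mu2": 0.25, "lam": float("inf")})
traj = run(params, T=2000, seed=11)
summary = summarize_window(traj, window=500)
```

This prints (via the summary fields):

```
mean_C          4.0
gini_I          0.0
sd_sigma        0.0
regime          equilibrium
elite_structure equal
mean_f          [0.15 0.15 0.15 0.15 0.1  0.1  0.1  0.1 ]
mean_X          [1. 1. 1. 1. 5. 5. 5. 5.]
```

The society froze into an equilibrium in which four groups form a
coalition of equal elites: each cooperator keeps a single contributor
(the club good, not own production, is its income) and holds power 0.15,
while the four counter-elite groups each sustain five contributors of
their own public good and hold power 0.10. `gini_I = 0` and
`sd_sigma = 0` say the coalition is internally equal in both power and
effort. At higher `ε` the same society collapses to a single cooperating
group; at `ε = 0` with a stronger club good it enters persistent
non-equilibrium turnover instead.

The same run from a shell:

```sh
polisoc run --config params.json --seed 11 --steps 2000 --window 500 --out results/
polisoc sweep --config sweep.json --out results/sweep   # factorial, resumable
polisoc region-scan --config params.json --axis R2      # analytic regions
polisoc fixtures                                        # micro-society catalogue
```

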