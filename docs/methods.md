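# Methods

## The model

A society contains `G` groups with fixed sizes `n_j` and dynamically
changing political powers `f_j` (`0 ≤ f_j ≤ 1`, `Σ_j f_j = 1`). Each
discrete time step has four phases.

**1. Within-group public-goods game.** Each individual `i` of group `j`
holds a binary contribution strategy `x_ij ∈ {0, 1}`; contributing costs
`c` out of the baseline endowment `π⁰`. The group's combined effort
`X_j = Σ_i x_ij` produces

    P_j = B1 · X_j / (X_j + X0),

a saturating production function with maximum `B1` and half-effort `X0`
(diminishing marginal returns, partial participation supported).

**2. Between-group club-goods game.** Each group holds a status
`θ_j ∈ {0, 1}`. Cooperating groups (the "elites") pool their production
`Z = Σ_{θ_j=1} P_j` into a club good

    Q = B2 · Z / (Z + Z0),

divided among coalition members in proportion to power:
`v_j = f_j / Σ_{k∈coalition} f_k`. Defecting groups keep their own `P_j`.
A group with `X_j = 0` can never be a coalition member (membership rule).
Group payoff: `Π_j = n_j π⁰ − c X_j + P_j` (defector) or `+ v_j Q`
(cooperator). Each member receives a `1/n_j^α` share of the group's
resource term, where `α ∈ [0, 1]` is the rivalrousness of the goods
(`α = 1` fully rival, `α = 0` pure public).

**3. Political contest.** Each group exerts effective political effort

    y_j = Π_j · (1 − ε + ε f_j),

where the incumbency parameter `ε ∈ [0, 1]` controls how strongly current
power amplifies effort (small `ε` = strong checks-and-balances). Next-step
powers follow the Tullock contest success function `f'_j = y_j / Σ_k y_k`
(uniform `1/G` if all efforts vanish). Because `c ≤ π⁰` is enforced at
construction, `Π_j ≥ 0` always and the contest is well defined; a negative
payoff raises rather than being clipped.

**4. Strategy revision** (actually executed *first* within a step, so that
payoffs are realized on the revised strategies). Each individual revises
with probability `μ1` and each group with probability `μ2`, by myopic best
response with logit errors: the actor compares the payoffs of its two
actions computed against the pre-revision state — everything else held
fixed, including powers (no anticipation of the contest) — and picks
action 1 with probability `1/(1 + exp(−λΔ))`. `λ = ∞` (the default, and
the case all headline results use) is the exact best response with fair
coin tie-breaks. Individuals revise synchronously first, then groups; the
membership rule is enforced after group revision every step.

Two readings of the hypothetical evaluation were genuinely open and are
resolved as follows. (a) An individual whose withdrawal would leave its
group with zero effort evaluates that branch with the group forced out of
the coalition and producing nothing — the membership rule applies inside
the hypothetical. (b) A member of a cooperating group does account for the
effect of its own contribution on the coalition pool `Z` and hence on `Q`
(the club-good branch of the payoff depends on `Q`, which depends on
`X_j`; a full recomputation is the only self-consistent reading). A group
considering joining an empty coalition evaluates `v_j = 1`.

## Randomness and reproducibility

Selection uniforms for all actors are drawn first (canonical order: group
index, then member index), then action uniforms for all actors — one draw
each whether or not the actor was selected. Runs are therefore
bit-reproducible from a seed, and the revision outcome does not depend on
the order in which actors are evaluated. Ensembles spawn one child
`SeedSequence` per run index from a master seed; parameter sweeps spawn
one child per parameter combination, so an interrupted sweep resumes to
exactly the results a fresh full sweep would produce.

## Initial conditions and protocol

Initial powers follow a broken-stick partition of [0, 1] (G−1 uniform
cuts, segment lengths in position order — labels are exchangeable, so
sorting would not change any summary) when groups have equal sizes, and
equal powers `1/G` otherwise. Each individual and group initially
cooperates with probability 0.5. The reference protocol runs 100–200
seeded replicates of 4000 steps and averages the last 1000; the default
desk scale used by the test suite and the acceptance script is 10
replicates of 1000 steps averaging the last 250, which the sweeps here
showed is past the burn-in of every configuration exercised. Both scales
are plain configuration values.

## Summary statistics

Per step, restricted to cooperating groups: coalition size `C`, Gini
index `I` of powers (half of the relative mean absolute difference;
undefined and excluded from averages when `C = 0`, zero when `C = 1`),
and the population standard deviation `σ` of efforts (population rather
than sample because the cooperators are the entire population of
interest). A run is classified *equilibrium* when every `x_ij` and `θ_j`
is constant over the averaging window and every power stays within
`f_tol = 1e-6` of its window mean (power converges geometrically once
strategies freeze, so the tolerance is generous); anything else is
*non-equilibrium*. This operationalizes the observation that window-mean
statuses strictly between 0 and 1 indicate persistent fluctuations.
Equilibrium coalitions are classified by 1-D gap clustering of mean
powers with gap width `power_tol = 1e-3`: one class = equal elites, two =
dominant/subordinate; three or more contradicts the model's equilibrium
taxonomy and raises an error rather than silently reporting a structure.

## Closed-form approximations

Treating contributions as continuous:

- Isolated group: positive effort requires `b1 > c(1 + X0)` with
  `b1 = B1/n^α`; with `R1 = B1/(c X0)` the stationary effort is `X* = 0`
  if `R1 < n^α`, else `min{n, X0(√(R1/n^α) − 1)}`.
- All-defect state (`C = 0`): exists iff `R2 < 1 + ω R1 (1 − √(n^α/R1))`
  with `R2 = B2/Z0`, `ω = c X0/Z0`; stable to small power perturbations
  for `ε < 1`.
- Symmetric coalition of `C` groups:
  `X_c* = X0/(ω C R1 + 1) · (√(R1 R2/(C n^α)) − 1)`, positive iff
  `R1 R2 > C n^α`. A member does not defect iff
  `R1 < n^α (C R2/4)(1 + √(1 + 4/(C² n^α ω)(1 − 1/R2)))²`; when `R2 ≤ 1`
  makes the inner root negative the condition is reported inapplicable
  (False) rather than raising.
- Full coalition (`C = G`): stable to small power perturbations iff
  `ε < ε_max = A_c*/(A_c* + Q_G/G²)`, with `A_c* = n π⁰ − c X_c*` and
  `Q_G` the club good produced when every group contributes `P(X_c*)`.
  `Q_G` and `A_c*` are obtained by composing the coalition-effort,
  production and club-good formulas under symmetry.

For partial coalitions (`0 < C < G`) the incumbency bounds `ε_min`,
`ε_max` are defined only implicitly; this package does not re-derive
them. Instead a numerical probe freezes strategies at the symmetric
candidate (integer-rounded effort), perturbs one cooperator's power by
`δ` (default 1e-3, renormalized), iterates the payoff → effort → contest
map, and declares stability when the maximum deviation falls below
`δ/10` within the horizon. `eps_max_numeric` bisects the probe on
`ε ∈ [0, 1]` to 1e-3. The probe and the closed form agree to a few
hundredths at `C = G`; the residual gap comes from the integer rounding
of the probe's candidate state.

## Numerical choices

- Analytic efforts are reported as continuous values; comparisons with
  simulation round to the nearest integer in `[0, n]` and use a ±1
  contributor tolerance.
- The power-sum invariant is checked to 1e-12 and violations are errors;
  states are never silently renormalized (the contest normalizes exactly
  up to rounding).
- A coalition whose total power is exactly zero (only reachable
  transiently from degenerate power vectors) divides the club good
  equally — the symmetric limit of the proportional rule, avoiding 0/0.
- The logit rule guards `exp` overflow by saturating at ±700 in the
  exponent; `λ = ∞` is an explicit sentinel, not a large float.
- Ensemble confidence intervals are mean ± 1.96 SE across runs.

## What the synthetic experiments do and do not show

All inputs are generated by the model itself; there is no empirical
calibration. Passing tests show internal consistency (simulation agrees
with the independent closed forms and brute-force best responses, and
reproduces the model's qualitative comparative statics) at desk scale.
They do not show that real societies behave this way: group sizes are
fixed, parameters time-invariant, actors purely material-payoff-driven
and myopic, and there is no spatial or network structure, reputation,
punishment, or coalition-formation cost.

## Known limitations

- Partial-coalition stability bounds are numerical only (see above).
- The regime classifier is a reconstruction; runs that freeze strategies
  but drift in power slower than `f_tol` over a short window could be
  misclassified — the defaults were chosen so this does not occur in any
  configuration the suite exercises.
- With `λ` finite the dynamics mix over all states and "equilibrium" in
  the strict classifier sense rarely obtains; finite-`λ` behavior is
  exercised only as a smoke test.
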