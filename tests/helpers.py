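"""From-scratch reference implementations used as test oracles.

Everything here is written directly from the model's payoff definitions in
plain Python (no reuse of the package's game functions), so oracle tests
check the implementation against an independent evaluation path.
"""

from __future__ import annotations

import math


def oracle_payoffs(x_groups, theta, f, B1, X0, B2, Z0, c, pi0, alpha,
                   group_sizes):
    """Direct evaluation of all group and individual payoffs.

    Parameters are scalars and plain lists; ``x_groups`` is a list of
    per-group contribution lists. Returns (Pi per group, pi per group as
    nested lists).
    """
    G = len(group_sizes)
    X = [sum(xs) for xs in x_groups]
    P = [B1 * Xj / (Xj + X0) if Xj > 0 else 0.0 for Xj in X]
    # membership rule: effortless groups cannot cooperate
    th = [theta[j] if X[j] > 0 else 0 for j in range(G)]
    coop = [j for j in range(G) if th[j] == 1]
    Z = sum(P[j] for j in coop)
    Q = B2 * Z / (Z + Z0) if coop else 0.0
    F = sum(f[j] for j in coop)
    v = [0.0] * G
    for j in coop:
        v[j] = f[j] / F if F > 0 else 1.0 / len(coop)
    Pi, pi = [], []
    for j in range(G):
        n = group_sizes[j]
        res = v[j] * Q if th[j] == 1 else P[j]
        Pi.append(n * pi0 - c * X[j] + res)
        pi.append([pi0 - c * xi + res / n ** alpha for xi in x_groups[j]])
    return Pi, pi


def oracle_gini(values):
    """Half of the relative mean absolute difference, by double loop."""
    m = len(values)
    mean = sum(values) / m
    mad = sum(abs(a - b) for a in values for b in values)
    return mad / (2 * m * m * mean)


def oracle_eps_max_chain(R1, R2, omega, n, G, c, pi0, X0, Z0, alpha):
    """Incumbency ceiling for the full coalition, composed step by step.

    Symmetric coalition effort -> per-group production -> club good ->
    ceiling, all evaluated directly from the formulas.
    """
    Xc = X0 / (omega * G * R1 + 1) * (math.sqrt(R1 * R2 / (G * n ** alpha))
                                      - 1)
    assert Xc > 0
    B1 = R1 * c * X0
    B2 = R2 * Z0
    P = B1 * Xc / (Xc + X0)
    Z_G = G * P
    Q_G = B2 * Z_G / (Z_G + Z0)
    A_c = n * pi0 - c * Xc
    return A_c / (A_c + Q_G / G ** 2)
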