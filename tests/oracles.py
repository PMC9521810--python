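"""Independent numerical oracles used only by the tests.

These deliberately avoid the package's analytic equilibrium expressions:
the single-ligand oracle brackets the mass-action fixed point with
bisection, and the competitive oracle runs a damped fixed-point iteration
on the free-species equations, so agreement with the package is a real
cross-check rather than a tautology.
"""

import numpy as np
from scipy.optimize import bisect


def complex_2c_bisection(Rt, Lt, Kd):
    """[RL] from bisection on f(RL) = (Rt-RL)(Lt-RL)/Kd - RL."""
    if Rt == 0 or Lt == 0:
        return 0.0
    hi = min(Rt, Lt)

    def f(rl):
        return (Rt - rl) * (Lt - rl) / Kd - rl

    return bisect(f, 0.0, hi, xtol=1e-300, rtol=1e-15)


def complex_competitive_fixed_point(Rt, L1t, L2t, Kd1, Kd2, damping=0.5,
                                    tol=1e-14, max_iter=100000):
    """(RL1, RL2) from damped fixed-point iteration on the free species."""
    R = Rt
    for _ in range(max_iter):
        L1 = L1t / (1.0 + R / Kd1)
        L2 = L2t / (1.0 + R / Kd2)
        R_new = Rt / (1.0 + L1 / Kd1 + L2 / Kd2)
        R = damping * R_new + (1.0 - damping) * R
        if abs(R_new - R) <= tol * max(R, 1e-300):
            break
    L1 = L1t / (1.0 + R / Kd1)
    L2 = L2t / (1.0 + R / Kd2)
    return R * L1 / Kd1, R * L2 / Kd2


def heats_loop(theta_vec, model, injection_volumes, V0, T, equilibrium):
    """Direct per-injection summation of the heat bookkeeping.

    ``equilibrium`` maps (Rt, L1t, L2t) -> (RL1, RL2); the loop tracks the
    cumulative dilution explicitly instead of vectorized products.
    """
    R_GAS = 1.9872e-3
    q = []
    d = 1.0
    prev = (0.0, 0.0)
    for dv in injection_volumes:
        dprime = 1.0 - dv / V0
        d *= dprime
        if model == "2C":
            dG, dH, dH0, R0, Ls, _ = theta_vec
            rl1, rl2 = equilibrium(R0 * d, Ls * (1 - d), 0.0), 0.0
            dh1, dh2 = dH * 1000, 0.0
        else:
            dG1, ddG, dH1, dH2, dH0, R0, Ls, rho, _ = theta_vec
            lig = Ls * (1 - d)
            rl1, rl2 = equilibrium(R0 * d, rho * lig, (1 - rho) * lig)
            dh1, dh2 = dH1 * 1000, dH2 * 1000
        qn = V0 * (dh1 * (rl1 - dprime * prev[0]) + dh2 * (rl2 - dprime * prev[1]))
        q.append(qn + dH0)
        prev = (rl1, rl2)
    return np.array(q)
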