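"""Independent numerical oracles used by the tests.

The ODE oracle integrates the growth/consumption equations directly with an
adaptive solver and event detection, sharing no code with the event-driven
sum-of-exponentials solver it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from diauxie.traits import pool_arrays


def ode_cycle(pool, n0, supply, rtol=1e-11):
    """Depletion times and end populations by direct ODE integration.

    Returns (t_dep, n_end): per-resource depletion times within the cycle
    (0 for zero supply) and the end-of-cycle populations.
    """
    g, pref, _ = pool_arrays(pool)
    S, R = g.shape
    n = np.asarray(n0, dtype=float).copy()
    c = np.asarray(supply, dtype=float).copy()
    avail = c > 0.0
    t = 0.0
    t_dep = np.zeros(R)
    while avail.any():
        assign = np.full(S, -1)
        for m in range(S):
            if n[m] <= 0:
                continue
            for r in pref[m]:
                if avail[r]:
                    assign[m] = r
                    break

        def rhs(_, y):
            dn = np.zeros(S)
            dc = np.zeros(R)
            for m in range(S):
                r = assign[m]
                if r >= 0:
                    rate = g[m, r] * y[m]
                    dn[m] = rate
                    dc[r] -= rate
            return np.concatenate([dn, dc])

        avail_idx = [i for i in range(R) if avail[i]]

        def make_event(i):
            def ev(_, y):
                return y[S + i]

            ev.terminal = True
            ev.direction = -1
            return ev

        events = [make_event(i) for i in avail_idx]
        y0 = np.concatenate([n, c])
        sol = solve_ivp(
            rhs, (0.0, 1e4), y0, events=events, rtol=rtol, atol=1e-14, method="RK45"
        )
        if sol.status != 1:
            raise RuntimeError("oracle integration did not reach a depletion event")
        dt = sol.t[-1]
        y = sol.y[:, -1]
        n = y[:S]
        c = y[S:]
        t += dt
        for i in avail_idx:
            if c[i] <= max(1e-12, 1e-9 * supply[i]):
                c[i] = 0.0
                avail[i] = False
                t_dep[i] = t
    return t_dep, n


def sphere_max_oracle(tau, n_starts=64, seed=0):
    """Numerically maximize sum_k g_k tau_k over the unit sphere, g >= 0."""
    from scipy.optimize import minimize

    tau = np.asarray(tau, dtype=float)
    k = tau.size
    rng = np.random.default_rng(seed)
    best, best_val = None, -np.inf

    def neg(x):
        g = np.abs(x)
        nrm = np.linalg.norm(g)
        if nrm == 0:
            return 0.0
        return -float(np.dot(g / nrm, tau))

    for _ in range(n_starts):
        x0 = rng.random(k) + 1e-3
        res = minimize(neg, x0, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14})
        if -res.fun > best_val:
            best_val = -res.fun
            g = np.abs(res.x)
            best = g / np.linalg.norm(g)
    return best
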