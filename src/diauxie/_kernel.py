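"""Numerical kernels for the event-driven growth-cycle solver.

Within one phase of a growth cycle every extant species consumes a single
fixed resource, so each concentration follows

    c_i(t0 + dt) = c_i(t0) - sum_{mu eating i} n_mu(t0) * (exp(g_mu_i dt) - 1)

which is monotone decreasing and convex in dt.  Depletion times are found by
Newton iteration started from the guaranteed upper bracket
``log1p(c_i / n_tot) / g_min`` (consumption computed with every eater at the
slowest eater's rate underestimates consumption, hence overestimates the
depletion time); for a convex increasing function Newton from above converges
monotonically, so the bracket is never left.

The kernels are compiled with numba when available and run as plain Python
otherwise (identical results, much slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


# Status codes returned by the kernels.
OK = 0
STALL = 1  # resources remain but nothing eats them
ALL_EXTINCT = 2


@njit(cache=True)
def depletion_time(n, g, assign, i, c_i, t_tol):
    """Time for resource ``i`` to hit zero given fixed eater assignment.

    ``assign[m]`` is the resource species ``m`` eats this phase (-1 = none).
    Returns inf when the resource has no eaters, 0.0 when already depleted.
    """
    if c_i <= 0.0:
        return 0.0
    # Upper bracket: the depletion time ignoring all but one eater, minimized
    # over eaters.  Total consumption dominates each single contribution, so
    # this bounds the root from above, and it keeps every exponent in the
    # Newton iteration at exp(g_m x) <= 1 + c_i / n_m (no overflow).
    x = np.inf
    for m in range(n.shape[0]):
        if assign[m] == i and n[m] > 0.0:
            t_m = np.log1p(c_i / n[m]) / g[m, i]
            if t_m < x:
                x = t_m
    if not np.isfinite(x):
        return np.inf
    for _ in range(200):
        f = -c_i
        fp = 0.0
        for m in range(n.shape[0]):
            if assign[m] == i and n[m] > 0.0:
                e = np.exp(g[m, i] * x)
                f += n[m] * (e - 1.0)
                fp += n[m] * g[m, i] * e
        dx = f / fp
        x -= dx
        if abs(dx) <= t_tol:
            break
    if x < 0.0:
        x = 0.0
    return x


@njit(cache=True)
def run_cycle(n0, g, pref, supply, t_tol):
    """Run one full growth cycle to complete depletion of all supplied resources.

    Parameters
    ----------
    n0 : (S,) start-of-cycle populations (post-mortality carryover)
    g : (S, R) growth rates
    pref : (S, R) preference permutations, rank -> resource index
    supply : (R,) resource pulse; zero-supply resources count as depleted at t=0
    t_tol : absolute time tolerance of the event solver (hours)

    Returns
    -------
    (n_end, t_dep, dep_order, phase_t, eater_phase, phase_mask, n_phases, status)
        n_end       (S,) end-of-cycle populations (pre-mortality)
        t_dep       (R,) within-cycle depletion times (0 for zero supply)
        dep_order   (R,) resource indices in depletion order (-1 padding;
                    zero-supply resources are excluded)
        phase_t     (R+1,) phase boundary times, phase_t[n_phases] = cycle length
        eater_phase (R, S) resource eaten by each species in each phase (-1)
        phase_mask  (R,) bitmask of available resources during each phase
        n_phases    number of phases actually realized
        status      OK, STALL or ALL_EXTINCT
    """
    S, R = g.shape
    n = n0.copy()
    c = supply.copy()
    avail = np.zeros(R, np.bool_)
    for i in range(R):
        avail[i] = c[i] > 0.0
    t_dep = np.zeros(R)
    dep_order = np.full(R, -1, np.int64)
    ndep = 0
    phase_t = np.zeros(R + 1)
    eater_phase = np.full((R, S), -1, np.int64)
    phase_mask = np.zeros(R, np.int64)
    nph = 0
    t = 0.0
    status = OK
    dts = np.empty(R)
    cons = np.empty(R)
    while True:
        navail = 0
        mask = 0
        for i in range(R):
            if avail[i]:
                navail += 1
                mask |= 1 << i
        if navail == 0:
            break
        alive = 0
        for m in range(S):
            if n[m] <= 0.0:
                continue
            alive += 1
            for k in range(R):
                r = pref[m, k]
                if avail[r]:
                    eater_phase[nph, m] = r
                    break
        if alive == 0:
            status = ALL_EXTINCT
            break
        dt_min = np.inf
        for i in range(R):
            dts[i] = np.inf
            if avail[i]:
                dts[i] = depletion_time(n, g, eater_phase[nph], i, c[i], t_tol)
                if dts[i] < dt_min:
                    dt_min = dts[i]
        if not np.isfinite(dt_min):
            status = STALL
            break
        for i in range(R):
            cons[i] = 0.0
        for m in range(S):
            r = eater_phase[nph, m]
            if r < 0:
                continue
            e = np.exp(g[m, r] * dt_min)
            cons[r] += n[m] * (e - 1.0)
            n[m] *= e
        t += dt_min
        phase_t[nph + 1] = t
        phase_mask[nph] = mask
        for i in range(R):
            if not avail[i]:
                continue
            if dts[i] <= dt_min * (1.0 + 1e-12) + t_tol:
                c[i] = 0.0
            else:
                c[i] -= cons[i]
            if c[i] <= 1e-14:
                c[i] = 0.0
                avail[i] = False
                t_dep[i] = t
                dep_order[ndep] = i
                ndep += 1
        nph += 1
    return n, t_dep, dep_order, phase_t, eater_phase, phase_mask, nph, status


@njit(cache=True)
def run_block(
    n,
    g,
    pref,
    rank_of,
    supplies,
    mortality,
    ext_thresh,
    t_tol,
    frac_from,
    frac_out,
    tau_from,
    tau_out,
    niche_from,
    niche_count,
    niche_dur,
    ext_cycle,
    cycle_offset,
):
    """Run a block of growth cycles in place, with mortality and extinction.

    ``n`` is modified in place and holds the post-mortality populations after
    the block.  ``supplies`` is (K, R), one pre-sampled pulse per cycle.
    End-of-cycle fractions for cycles >= ``frac_from`` (block-local index) are
    written to ``frac_out``; per-species, per-preference-rank growth time for
    cycles >= ``tau_from`` accumulates into ``tau_out``; temporal-niche
    occurrence counts / durations (indexed by availability bitmask) for cycles
    >= ``niche_from`` accumulate into ``niche_count`` / ``niche_dur`` when
    those arrays are non-empty.  ``ext_cycle[m]`` records the global cycle
    index at which species ``m`` was pruned (-1 = never).

    Returns (status, cycles_completed).
    """
    K = supplies.shape[0]
    S = n.shape[0]
    for k in range(K):
        n_end, t_dep, dep_order, phase_t, eater_phase, phase_mask, nph, status = run_cycle(
            n, g, pref, supplies[k], t_tol
        )
        if status != OK:
            return status, k
        tot = 0.0
        for m in range(S):
            n[m] = n_end[m]
            tot += n[m]
        if tot <= 0.0:
            return ALL_EXTINCT, k
        if k >= frac_from:
            for m in range(S):
                frac_out[k - frac_from, m] = n[m] / tot
        if k >= tau_from:
            for p in range(nph):
                dur = phase_t[p + 1] - phase_t[p]
                for m in range(S):
                    r = eater_phase[p, m]
                    if r >= 0:
                        tau_out[m, rank_of[m, r]] += dur
        if niche_count.shape[0] > 0 and k >= niche_from:
            for p in range(nph):
                niche_count[phase_mask[p]] += 1
                niche_dur[phase_mask[p]] += phase_t[p + 1] - phase_t[p]
        for m in range(S):
            if n[m] > 0.0 and n[m] / tot < ext_thresh:
                n[m] = 0.0
                ext_cycle[m] = cycle_offset + k
        for m in range(S):
            n[m] /= mortality
    return OK, K
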