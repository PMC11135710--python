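"""Experiment orchestration: survivor determination, sweeps, scaling fits.

The survivor protocol mirrors how coexistence is scored in fluctuating
environments: five independent runs guard against early stochastic
extinctions; the union of their survivors then receives a ~10^3-fold inoculum
head start in three further runs (also an invasibility check), and species
surviving at least two of those three are reported.  A trend filter replaces
by-eye inspection of time traces: species whose log10 fraction is still
declining steadily toward the extinction threshold at the end of a run are
not counted as survivors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import Trajectory, equal_inoculum, run_serial_dilution
from .pools import PoolSpec, pool_size, sample_pool
from .supply import (
    ConstantSupply,
    SeasonalSupply,
    StochasticSupply,
    SupplySchedule,
    UniformSimplexSupply,
)
from .traits import SpeciesTraits, pool_arrays

__all__ = [
    "ProtocolConfig",
    "SurvivorReport",
    "DiversityFit",
    "survivor_protocol",
    "ce_violation_sweep",
    "diversity_scaling",
    "fit_diversity_law",
    "seasonal_assembly",
    "classify_dynamics",
    "flag_declining",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Settings of the repetition protocol and the underlying runs."""

    n_cycles: int = 10_000
    n_runs: int = 5
    n_headstart_runs: int = 3
    headstart_factor: float = 1e3
    min_headstart_survival: int = 2
    mortality: float = 10.0
    extinction_threshold: float = 1e-12
    trend_window: float = 0.2  # final fraction of cycles used by the trend filter
    trend_slope: float = -1e-4  # log10 fraction per cycle
    trend_fraction: float = 0.05  # only species below this can be filtered
    tau_window: float = 0.2


@dataclass
class SurvivorReport:
    """Reported survivors of one community under one supply schedule."""

    community_id: str
    n_resources: int
    survivors: list[str]
    survivor_traits: list[SpeciesTraits]
    per_run_survivors: list[set[str]]  # the initial independent runs
    per_headstart_survivors: list[set[str]]
    tau_time: np.ndarray  # per-rank mean hours/cycle of reported survivors
    n_anomalous_survivors: int

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)

    @property
    def ce_violation(self) -> bool:
        return self.n_survivors > self.n_resources


def flag_declining(
    fractions: np.ndarray,
    species_ids: Sequence[str],
    extant: np.ndarray,
    slope_threshold: float = -1e-4,
    fraction_threshold: float = 0.05,
) -> set[str]:
    """Species still extant but steadily trending toward extinction.

    Fits the slope of log10(fraction) over the recorded window; a species is
    flagged when the slope is below ``slope_threshold`` (per cycle) and its
    final fraction is already below ``fraction_threshold``.
    """
    flagged: set[str] = set()
    W = fractions.shape[0]
    x = np.arange(W, dtype=float)
    for m in np.nonzero(extant)[0]:
        f = fractions[:, m]
        if f[-1] >= fraction_threshold or np.any(f <= 0):
            continue
        slope = np.polyfit(x, np.log10(f), 1)[0]
        if slope < slope_threshold:
            flagged.add(species_ids[m])
    return flagged


def _run_survivors(traj: Trajectory, config: ProtocolConfig) -> set[str]:
    survivors = set(traj.survivors)
    flagged = flag_declining(
        traj.fractions,
        traj.species_ids,
        traj.survivor_mask,
        config.trend_slope,
        config.trend_fraction,
    )
    return survivors - flagged


def survivor_protocol(
    pool: Sequence[SpeciesTraits],
    schedule: SupplySchedule,
    seed: int,
    config: ProtocolConfig = ProtocolConfig(),
    community_id: str = "community",
) -> SurvivorReport:
    """Run the full repetition protocol on one community.

    Deterministic schedules make repeated runs identical, so each repetition
    group is simulated once and reused.
    """
    g, pref, ids = pool_arrays(pool)
    S, R = g.shape
    # the trend filter fits a slope over the final window; 2000 cycles is
    # ample for that, and capping it bounds the fraction buffer for large
    # pools on long runs
    record_last = max(100, min(int(round(config.trend_window * config.n_cycles)), 2000))
    seeds = np.random.SeedSequence(seed).spawn(config.n_runs + config.n_headstart_runs)

    def one_run(seq, inoculum) -> Trajectory:
        return run_serial_dilution(
            pool,
            schedule,
            config.n_cycles,
            rng=np.random.default_rng(seq),
            initial_populations=inoculum,
            mortality=config.mortality,
            extinction_threshold=config.extinction_threshold,
            record="window",
            record_last=record_last,
            tau_window=config.tau_window,
            tally_niches=False,
        )

    inoc = equal_inoculum(S)
    if schedule.stochastic:
        initial = [one_run(seeds[k], inoc) for k in range(config.n_runs)]
    else:
        initial = [one_run(seeds[0], inoc)] * config.n_runs
    per_run = [_run_survivors(t, config) for t in initial]
    union = sorted(set().union(*per_run))
    if not union:
        raise RuntimeError(f"{community_id}: no survivors in any initial run")

    head = np.array([sid in set(union) for sid in ids], dtype=float)
    inoc_hs = 1.0 + (config.headstart_factor - 1.0) * head
    inoc_hs *= inoc.sum() / inoc_hs.sum()
    if schedule.stochastic:
        head_runs = [
            one_run(seeds[config.n_runs + k], inoc_hs)
            for k in range(config.n_headstart_runs)
        ]
    else:
        head_runs = [one_run(seeds[config.n_runs], inoc_hs)] * config.n_headstart_runs
    per_head = [_run_survivors(t, config) for t in head_runs]

    votes: dict[str, int] = {}
    for surv in per_head:
        for sid in surv:
            votes[sid] = votes.get(sid, 0) + 1
    reported = sorted(s for s, v in votes.items() if v >= config.min_headstart_survival)
    id_to_sp = {sp.species_id: sp for sp in pool}
    traits = [id_to_sp[s] for s in reported]

    if reported:
        tau_stack = [
            t.tau_time[[t.species_ids.index(s) for s in reported]] for t in head_runs
        ]
        tau = np.mean([ts.mean(axis=0) for ts in tau_stack], axis=0)
    else:
        tau = np.zeros(R)

    return SurvivorReport(
        community_id=community_id,
        n_resources=R,
        survivors=reported,
        survivor_traits=traits,
        per_run_survivors=per_run,
        per_headstart_survivors=per_head,
        tau_time=tau,
        n_anomalous_survivors=sum(sp.anomalous for sp in traits),
    )


def _schedule_for_sigma(sigma: float) -> SupplySchedule:
    if sigma == 0.0:
        return ConstantSupply(3)
    return StochasticSupply(sigma)


def ce_violation_sweep(
    pools: Sequence[Sequence[SpeciesTraits]],
    sigmas: Sequence[float],
    seed: int,
    config: ProtocolConfig = ProtocolConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Competitive-exclusion violation frequency across fluctuation magnitudes.

    The same pools are reused at every magnitude.  Returns a summary frame
    (sigma_rs, violation_fraction, mean_survivors, sem_survivors) and the
    per-(sigma, pool) :class:`SurvivorReport` objects.
    """
    rows = []
    reports: dict[tuple[float, int], SurvivorReport] = {}
    ss = np.random.SeedSequence(seed)
    pool_seeds = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(len(pools))]
    for sigma in sigmas:
        schedule = _schedule_for_sigma(float(sigma))
        counts = []
        for j, pool in enumerate(pools):
            rep = survivor_protocol(
                pool, schedule, pool_seeds[j], config, community_id=f"pool{j:03d}"
            )
            reports[(float(sigma), j)] = rep
            counts.append(rep.n_survivors)
        counts_arr = np.array(counts, dtype=float)
        n_res = pools[0][0].n_resources
        rows.append(
            {
                "sigma_rs": float(sigma),
                "n_pools": len(pools),
                "violation_fraction": float(np.mean(counts_arr > n_res)),
                "mean_survivors": float(counts_arr.mean()),
                "sem_survivors": float(counts_arr.std(ddof=1) / math.sqrt(len(counts)))
                if len(counts) > 1
                else 0.0,
            }
        )
    return pd.DataFrame(rows), reports


def diversity_scaling(
    resource_counts: Sequence[int],
    n_pools: int,
    seed: int,
    config: ProtocolConfig = ProtocolConfig(),
    pool_cap: int | None = 5000,
    density_constant: float = 500.0,
    pool_sizes: dict | None = None,
) -> pd.DataFrame:
    """Survivor counts across resource counts under uniform-random supply.

    Pools are rate-ordered (no anomalous species), sized by the
    constant-density rule capped at ``pool_cap``; ``pool_sizes`` overrides
    the size for individual resource counts (the rule's literal sizes are
    unaffordable beyond a few resources, and a flat cap suppresses the
    steep growth in pool size the rule prescribes).
    """
    rows = []
    for n_res in resource_counts:
        ss = np.random.SeedSequence([seed, n_res])
        if pool_sizes is not None and n_res in pool_sizes:
            n_sp = int(pool_sizes[n_res])
        else:
            n_sp = pool_size(n_res, density_constant, cap=pool_cap)
        schedule = UniformSimplexSupply(n_res)
        for j, child in enumerate(ss.spawn(n_pools)):
            pool_seed, proto_seed = (int(x >> 1) for x in child.generate_state(2))
            pool = sample_pool(
                PoolSpec(n_res, n_sp, preference_mode="rate-ordered", seed=pool_seed)
            )
            rep = survivor_protocol(
                pool, schedule, proto_seed, config, community_id=f"R{n_res}-pool{j}"
            )
            rows.append(
                {
                    "n_resources": n_res,
                    "pool": j,
                    "pool_size": n_sp,
                    "n_survivors": rep.n_survivors,
                    "ce_violation": rep.ce_violation,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DiversityFit:
    """One two-parameter fit of survivors vs resources."""

    family: str  # linear, monomial, exponential
    b1: float
    b2: float
    se_b1: float
    se_b2: float
    r_squared: float
    rms_error: float
    rss: float
    n: int

    def predict(self, n_resources: np.ndarray) -> np.ndarray:
        x = np.asarray(n_resources, dtype=float)
        if self.family == "linear":
            return self.b1 + self.b2 * x
        if self.family == "monomial":
            return self.b1 * x**self.b2
        return self.b1 * np.exp(self.b2 * x)


def _curve_fit(func, x, y, p0):
    popt, pcov = optimize.curve_fit(func, x, y, p0=p0, maxfev=20_000)
    se = np.sqrt(np.diag(pcov))
    resid = y - func(x, *popt)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return popt, se, rss, 1.0 - rss / tss if tss > 0 else 1.0


def fit_diversity_law(
    n_resources: np.ndarray,
    n_survivors: np.ndarray,
) -> dict:
    """Linear, monomial and exponential fits of survivors vs resources.

    Returns the three :class:`DiversityFit` objects, the best family by R^2
    (equivalently RMS error, as all families have two parameters), and the
    pairwise variance-ratio F-test p-values between the residual sums of
    squares (the conventional comparison for these non-nested, equal-size
    models).
    """
    x = np.asarray(n_resources, dtype=float)
    y = np.asarray(n_survivors, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct resource counts")
    n = x.size
    fits: dict[str, DiversityFit] = {}

    lin = np.polyfit(x, y, 1, cov=True)
    (b2, b1), cov = lin
    resid = y - (b1 + b2 * x)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    fits["linear"] = DiversityFit(
        "linear", float(b1), float(b2), float(np.sqrt(cov[1, 1])), float(np.sqrt(cov[0, 0])),
        1.0 - rss / tss, math.sqrt(rss / n), rss, n,
    )

    # log-log / semilog least squares provide the starting points
    pos = y > 0
    p_mono = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
    popt, se, rss_m, r2 = _curve_fit(lambda x, a, b: a * x**b, x, y, [math.exp(p_mono[1]), p_mono[0]])
    fits["monomial"] = DiversityFit(
        "monomial", float(popt[0]), float(popt[1]), float(se[0]), float(se[1]),
        r2, math.sqrt(rss_m / n), rss_m, n,
    )

    p_exp = np.polyfit(x[pos], np.log(y[pos]), 1)
    popt, se, rss_e, r2 = _curve_fit(
        lambda x, a, b: a * np.exp(b * x), x, y, [math.exp(p_exp[1]), p_exp[0]]
    )
    fits["exponential"] = DiversityFit(
        "exponential", float(popt[0]), float(popt[1]), float(se[0]), float(se[1]),
        r2, math.sqrt(rss_e / n), rss_e, n,
    )

    best = max(fits.values(), key=lambda f: f.r_squared).family
    df = n - 2
    f_tests = {}
    for a in fits:
        for b in fits:
            if a < b:
                hi, lo = max(fits[a].rss, fits[b].rss), min(fits[a].rss, fits[b].rss)
                f_stat = hi / lo if lo > 0 else np.inf
                f_tests[f"{a}_vs_{b}"] = {
                    "F": float(f_stat),
                    "p": float(stats.f.sf(f_stat, df, df)),
                }
    return {"fits": fits, "best": best, "f_tests": f_tests}


def seasonal_assembly(
    period: int,
    pools: Sequence[Sequence[SpeciesTraits]],
    seed: int,
    config: ProtocolConfig = ProtocolConfig(),
) -> tuple[float, list[SurvivorReport]]:
    """Survivor counts under the deterministic seasonal oscillation."""
    schedule = SeasonalSupply(period)
    ss = np.random.SeedSequence([seed, period])
    pool_seeds = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(len(pools))]
    reports = [
        survivor_protocol(pool, schedule, pool_seeds[j], config, community_id=f"seasonal{j}")
        for j, pool in enumerate(pools)
    ]
    return float(np.mean([r.n_survivors for r in reports])), reports


@dataclass(frozen=True)
class DynamicsClass:
    kind: str  # "fixed_point", "periodic", "aperiodic"
    period: int | None = None


def classify_dynamics(
    fractions: np.ndarray,
    fixed_point_tol: float = 1e-10,
    min_correlation: float = 0.99,
) -> DynamicsClass:
    """Classify post-burn-in end-of-cycle fraction dynamics.

    ``fractions`` is a (cycles, species) window after burn-in.  Fixed point:
    every per-species change between consecutive cycles stays below
    ``fixed_point_tol``.  Otherwise, periodic with period L if the fraction
    series at integer lag L has autocorrelation above ``min_correlation`` (the
    dominant such lag is reported).  Anything else is labelled aperiodic —
    a candidate for chaos, not a claim of it.
    """
    f = np.atleast_2d(np.asarray(fractions, dtype=float))
    W, S = f.shape
    if W < 4:
        raise ValueError("need at least 4 cycles to classify dynamics")
    if np.max(np.abs(np.diff(f, axis=0))) < fixed_point_tol:
        return DynamicsClass("fixed_point")
    centered = f - f.mean(axis=0)
    # lag-1 recurrence is the fixed-point case handled above, so candidate
    # periods start at 2; the smallest lag clearing the bar is the period
    for lag in range(2, W // 2 + 1):
        num = float(np.sum(centered[:-lag] * centered[lag:]))
        scale = float(np.sqrt(np.sum(centered[:-lag] ** 2) * np.sum(centered[lag:] ** 2)))
        corr = num / scale if scale > 0 else 0.0
        if corr > min_correlation:
            return DynamicsClass("periodic", period=lag)
    return DynamicsClass("aperiodic")
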