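"""Serial-dilution dynamics with sequential (diauxic) resource utilization.

The model: species grow exponentially on one resource at a time — whichever
available resource ranks highest in their preference order — with unit yield,
so populations obey ``dn_mu/dt = g_mu,r n_mu`` and concentrations
``dc_i/dt = -sum_{mu eating i} g_mu_i n_mu``.  When every supplied resource is
depleted the growth cycle ends: populations are divided by the mortality
factor (default 10), concentrations are reset to the next pulse ``s_i`` with
``sum_i s_i = 1``, and the next cycle begins.  At the attractor the total
end-of-cycle biomass is 10/9, so end-of-cycle population fractions equal
``(9/10) n_mu``.

Because growth is piecewise exponential the dynamics are solved exactly
event-by-event (sum-of-exponentials root finding) instead of by ODE
integration.  Species are pruned when their end-of-cycle population fraction
drops below the extinction threshold (default 1e-12).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _kernel
from .traits import SpeciesTraits, pool_arrays

__all__ = [
    "CommunityState",
    "CycleRecord",
    "Trajectory",
    "active_resource",
    "solve_phase",
    "run_growth_cycle",
    "apply_mortality_and_resupply",
    "population_fractions",
    "run_serial_dilution",
    "equal_inoculum",
    "StallError",
]

#: total inoculated biomass: the attractor's post-mortality carryover, since
#: one unit of resource is supplied per cycle and mortality divides by 10.
DEFAULT_INOCULUM_TOTAL = 1.0 / 9.0


class StallError(RuntimeError):
    """Raised when available resources remain but no extant species eats them."""


@dataclass
class CommunityState:
    """Populations and resource concentrations at a point in time."""

    populations: np.ndarray
    concentrations: np.ndarray
    cycle_index: int = 0
    time_in_cycle: float = 0.0

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.populations < 0) or np.any(self.concentrations < 0):
            raise ValueError("populations and concentrations must be non-negative")


@dataclass
class CycleRecord:
    """Exact event structure of one growth cycle."""

    cycle_index: int
    supply: np.ndarray
    depletion_times: np.ndarray  # (R,) time within cycle; 0 for zero supply
    depletion_order: list[int]  # supplied resources only
    phase_boundaries: np.ndarray  # (n_phases + 1,) starting at 0
    available_sets: list[frozenset[int]]  # per phase
    eater_map: np.ndarray  # (n_phases, S) resource eaten per species, -1 = none
    start_populations: np.ndarray
    end_populations: np.ndarray

    @property
    def cycle_length(self) -> float:
        return float(self.phase_boundaries[-1])

    @property
    def phase_durations(self) -> np.ndarray:
        return np.diff(self.phase_boundaries)


@dataclass
class Trajectory:
    """Outcome of a serial-dilution run.

    ``fractions`` holds end-of-cycle population fractions for the recorded
    cycles (rows align with ``recorded_cycles``).  ``tau_time`` is the
    per-species, per-preference-rank mean growth time (hours per cycle)
    averaged over the final ``tau_cycles`` cycles.  ``niche_counts`` /
    ``niche_durations`` tally temporal niches (keyed by frozenset of available
    resource indices) over the same window as ``fractions`` recording start.
    """

    species_ids: list[str]
    n_resources: int
    n_cycles: int
    recorded_cycles: np.ndarray
    fractions: np.ndarray
    extinction_cycle: np.ndarray  # (S,) global cycle index, -1 = extant
    final_populations: np.ndarray  # post-mortality, ready for a next cycle
    final_biomass: float  # end of last cycle, pre-mortality
    tau_time: np.ndarray  # (S, R) mean hours per cycle on each preference rank
    tau_cycles: int
    niche_counts: dict = field(default_factory=dict)
    niche_durations: dict = field(default_factory=dict)
    niche_cycles: int = 0
    records: list[CycleRecord] = field(default_factory=list)

    @property
    def survivor_mask(self) -> np.ndarray:
        return self.extinction_cycle < 0

    @property
    def survivors(self) -> list[str]:
        return [sid for sid, ok in zip(self.species_ids, self.survivor_mask) if ok]

    @property
    def extinctions(self) -> list[tuple[str, int]]:
        return [
            (sid, int(c))
            for sid, c in zip(self.species_ids, self.extinction_cycle)
            if c >= 0
        ]


def active_resource(traits: SpeciesTraits, available: Iterable[int]) -> int | None:
    """The resource ``traits`` eats given the set of still-available resources.

    Returns the available resource with the best (lowest) preference rank, or
    None when nothing is available.
    """
    avail = set(int(i) for i in available)
    for r in traits.preference_order:
        if int(r) in avail:
            return int(r)
    return None


def solve_phase(
    populations: np.ndarray,
    growth_rates: np.ndarray,
    assignment: np.ndarray,
    concentrations: np.ndarray,
    time_tol: float = 1e-12,
) -> tuple[float, list[int]]:
    """Next depletion event given a fixed species-to-resource assignment.

    ``assignment[m]`` is the resource species ``m`` consumes during the phase
    (-1 for none).  Returns ``(dt, depleted)``: the time from phase start to
    the earliest depletion, and every available resource depleted within the
    solver tolerance of that time.  Raises :class:`StallError` when no
    available resource has any eater.
    """
    n = np.ascontiguousarray(populations, dtype=float)
    g = np.ascontiguousarray(growth_rates, dtype=float)
    assign = np.ascontiguousarray(assignment, dtype=np.int64)
    c = np.asarray(concentrations, dtype=float)
    R = g.shape[1]
    dts = np.full(R, np.inf)
    for i in range(R):
        if c[i] > 0.0:
            dts[i] = _kernel.depletion_time(n, g, assign, i, float(c[i]), time_tol)
        elif np.any((assign == i) & (n > 0)):
            dts[i] = 0.0  # already-empty resource: immediate event
    dt = float(np.min(dts))
    if not np.isfinite(dt):
        raise StallError("no available resource has any eater; dynamics would stall")
    depleted = [i for i in range(R) if dts[i] <= dt * (1 + 1e-12) + time_tol]
    return dt, depleted


def run_growth_cycle(
    state: CommunityState,
    pool: Sequence[SpeciesTraits],
    supply: np.ndarray,
    time_tol: float = 1e-12,
) -> tuple[CycleRecord, CommunityState]:
    """Run one complete growth cycle and return its record and the end state.

    The returned state holds end-of-cycle (pre-mortality) populations with the
    concentrations fully depleted; apply :func:`apply_mortality_and_resupply`
    to start the next cycle.
    """
    g, pref, ids = pool_arrays(pool)
    supply = np.asarray(supply, dtype=float)
    if supply.shape != (g.shape[1],):
        raise ValueError("supply length must match the number of resources")
    if np.any(supply < 0):
        raise ValueError("supply values must be non-negative")
    n0 = np.ascontiguousarray(state.populations, dtype=float)
    if not np.any(n0 > 0):
        raise ValueError("at least one extant species is required")
    n_end, t_dep, dep_order, phase_t, eater_phase, phase_mask, nph, status = _kernel.run_cycle(
        n0, g, pref, supply, time_tol
    )
    if status == _kernel.STALL:
        raise StallError("no eater for remaining resources")
    if status == _kernel.ALL_EXTINCT:
        raise ValueError("no extant species")
    record = CycleRecord(
        cycle_index=state.cycle_index,
        supply=supply.copy(),
        depletion_times=t_dep,
        depletion_order=[int(i) for i in dep_order if i >= 0],
        phase_boundaries=phase_t[: nph + 1].copy(),
        available_sets=[
            frozenset(i for i in range(g.shape[1]) if phase_mask[p] >> i & 1)
            for p in range(nph)
        ],
        eater_map=eater_phase[:nph].copy(),
        start_populations=n0.copy(),
        end_populations=n_end,
    )
    end_state = CommunityState(
        populations=n_end,
        concentrations=np.zeros_like(supply),
        cycle_index=state.cycle_index,
        time_in_cycle=record.cycle_length,
    )
    return record, end_state


def apply_mortality_and_resupply(
    state: CommunityState,
    supply: np.ndarray,
    mortality: float = 10.0,
) -> CommunityState:
    """Dilution step between cycles: n -> n / mortality, c -> next supply."""
    if mortality <= 1.0:
        raise ValueError("mortality factor must exceed 1")
    return CommunityState(
        populations=state.populations / mortality,
        concentrations=np.asarray(supply, dtype=float).copy(),
        cycle_index=state.cycle_index + 1,
        time_in_cycle=0.0,
    )


def population_fractions(populations: np.ndarray) -> np.ndarray:
    """End-of-cycle population fractions n / sum(n).

    At the steady-state total biomass of 10/9 this equals (9/10) n.
    """
    n = np.asarray(populations, dtype=float)
    tot = n.sum()
    if tot <= 0:
        raise ValueError("total biomass must be positive")
    return n / tot


def equal_inoculum(n_species: int, total: float = DEFAULT_INOCULUM_TOTAL) -> np.ndarray:
    """Equal biomass per species, summing to the attractor carryover 1/9."""
    return np.full(n_species, total / n_species)


def run_serial_dilution(
    pool: Sequence[SpeciesTraits],
    schedule,
    n_cycles: int,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    initial_populations: np.ndarray | None = None,
    mortality: float = 10.0,
    extinction_threshold: float = 1e-12,
    time_tol: float = 1e-12,
    record: str = "window",
    record_last: int = 2000,
    tau_window: float = 0.2,
    tally_niches: bool = True,
    record_cycles: Iterable[int] = (),
) -> Trajectory:
    """Simulate ``n_cycles`` growth cycles of a community under ``schedule``.

    Parameters
    ----------
    pool : species definitions
    schedule : a supply schedule from :mod:`diauxie.supply` (must expose
        ``n_resources`` and ``batch(start, count, rng)``)
    n_cycles : number of growth cycles (>= 1)
    rng, seed : randomness for stochastic schedules; the run is deterministic
        given the seed and the schedule
    initial_populations : inoculum biomasses; default equal shares of 1/9
    record : ``"window"`` stores end-of-cycle fractions for the last
        ``record_last`` cycles, ``"all"`` stores every cycle, ``"none"`` only
        the last cycle
    tau_window : final fraction of cycles over which per-preference-rank
        growth times are averaged
    record_cycles : cycle indices for which full :class:`CycleRecord` event
        structures are kept
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    g, pref, ids = pool_arrays(pool)
    S, R = g.shape
    if schedule.n_resources != R:
        raise ValueError("schedule and pool disagree on the number of resources")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = (
        equal_inoculum(S)
        if initial_populations is None
        else np.asarray(initial_populations, dtype=float).copy()
    )
    if n.shape != (S,) or np.any(n < 0) or not np.any(n > 0):
        raise ValueError("initial populations must be non-negative with a positive total")

    rank_of = np.empty((S, R), dtype=np.int64)
    for k in range(R):
        rank_of[np.arange(S), pref[:, k]] = k

    supplies = np.ascontiguousarray(schedule.batch(0, n_cycles, rng), dtype=float)

    if record == "all":
        frac_from = 0
    elif record == "window":
        frac_from = max(0, n_cycles - int(record_last))
    elif record == "none":
        frac_from = n_cycles - 1
    else:
        raise ValueError("record must be 'all', 'window' or 'none'")
    tau_from = max(0, n_cycles - max(1, int(round(tau_window * n_cycles))))
    frac_out = np.zeros((n_cycles - frac_from, S))
    tau_out = np.zeros((S, R))
    if tally_niches and R <= 16:
        niche_count = np.zeros(2**R, dtype=np.int64)
        niche_dur = np.zeros(2**R)
        niche_from = frac_from
    else:
        niche_count = np.zeros(0, dtype=np.int64)
        niche_dur = np.zeros(0)
        niche_from = n_cycles
    ext_cycle = np.full(S, -1, dtype=np.int64)

    wanted = sorted(set(int(c) for c in record_cycles))
    if any(c < 0 or c >= n_cycles for c in wanted):
        raise ValueError("record_cycles out of range")
    records: list[CycleRecord] = []

    def run_span(start: int, stop: int) -> None:
        if stop <= start:
            return
        status, done = _kernel.run_block(
            n,
            g,
            pref,
            rank_of,
            supplies[start:stop],
            float(mortality),
            float(extinction_threshold),
            float(time_tol),
            frac_from - start,
            frac_out,
            tau_from - start,
            tau_out,
            niche_from - start,
            niche_count,
            niche_dur,
            ext_cycle,
            start,
        )
        if status == _kernel.STALL:
            raise StallError(f"dynamics stalled at cycle {start + done}")
        if status == _kernel.ALL_EXTINCT:
            raise ValueError(f"all species extinct at cycle {start + done}")

    # Block offsets shift the recording windows: run_block compares the
    # block-local index against (window_start - block_start).
    pos = 0
    for cyc in wanted:
        run_span(pos, cyc)
        rec_state = CommunityState(
            populations=n.copy(), concentrations=supplies[cyc].copy(), cycle_index=cyc
        )
        rec, end_state = run_growth_cycle(rec_state, pool, supplies[cyc], time_tol)
        records.append(rec)
        # replay the same cycle through the block kernel so that fraction /
        # tau / niche accounting stays uniform
        run_span(cyc, cyc + 1)
        pos = cyc + 1
    run_span(pos, n_cycles)

    # n holds post-mortality carryover; undo the last division to report the
    # end-of-cycle biomass (pruned species carried < 1e-12 of it)
    final_biomass = float(n.sum() * mortality)

    n_tau = n_cycles - tau_from
    tau_time = tau_out / n_tau

    counts: dict[frozenset[int], int] = {}
    durs: dict[frozenset[int], float] = {}
    if niche_count.shape[0]:
        for mask in np.nonzero(niche_count)[0]:
            key = frozenset(i for i in range(R) if mask >> i & 1)
            counts[key] = int(niche_count[mask])
            durs[key] = float(niche_dur[mask] / niche_count[mask])

    return Trajectory(
        species_ids=list(ids),
        n_resources=R,
        n_cycles=n_cycles,
        recorded_cycles=np.arange(frac_from, n_cycles),
        fractions=frac_out,
        extinction_cycle=ext_cycle,
        final_populations=n.copy(),
        final_biomass=final_biomass,
        tau_time=tau_time,
        tau_cycles=n_tau,
        niche_counts=counts,
        niche_durations=durs,
        niche_cycles=n_cycles - niche_from,
        records=records,
    )
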