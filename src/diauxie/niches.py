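"""Temporal-niche structure, richness bounds and optimal strategies.

Within one growth cycle resources deplete sequentially, so species pass
through a nested sequence of environments — first all supplied resources,
then all but one, and so on down to a single resource.  Each period during
which a particular subset of resources remains available is a *temporal
niche*.  Across cycles with varying depletion orders many distinct niches can
be realized; with N resources at most 2^N - 1 (every nonempty subset), which
bounds the number of stably coexisting species.

Given the mean time tau_k a species spends growing on its k-th preference per
cycle, the best growth-rate allocation under the metabolic constraint
``sum_k g_k^2 = 1`` maximizes ``sum_k g_k tau_k`` (log-growth per cycle is
linear in the rates), with the closed-form solution ``g* = tau / |tau|_2``.
Applied to every preference permutation this yields the set of optimal
strategies (6 for three resources) forming a "supersaturated" community.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

from .core import CycleRecord, Trajectory
from .traits import SpeciesTraits

__all__ = [
    "TemporalNiche",
    "NicheTally",
    "OptimalStrategy",
    "niches_of_cycle",
    "tally_niches",
    "max_niche_count",
    "time_on_preferences",
    "optimal_allocation",
    "optimal_strategy_set",
    "simplex_coordinates",
    "survivor_strategy_distance",
]


@dataclass(frozen=True)
class TemporalNiche:
    """A nonempty available-resource subset and the time spent in it."""

    available_resources: frozenset[int]
    duration: float

    def __post_init__(self) -> None:
        if not self.available_resources:
            raise ValueError("the all-depleted state is not a niche")


@dataclass
class NicheTally:
    """Distinct niches observed across cycles, with occupancy statistics."""

    counts: dict  # frozenset -> number of cycles in which the niche occurred
    mean_durations: dict  # frozenset -> mean duration per occurrence (hours)
    n_cycles: int
    n_resources: int

    @property
    def observed_niches(self) -> set[frozenset[int]]:
        return set(self.counts)

    @property
    def n_distinct(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class OptimalStrategy:
    """A preference permutation with the optimal growth-rate allocation on it."""

    preference_order: tuple[int, ...]
    growth_rates: np.ndarray  # unit L2 norm, indexed by resource


def max_niche_count(n_resources: int) -> int:
    """Upper bound on distinct temporal niches (and coexisting species): 2^N - 1."""
    if n_resources < 1:
        raise ValueError("need at least one resource")
    return 2**n_resources - 1


def niches_of_cycle(record: CycleRecord) -> list[TemporalNiche]:
    """Ordered temporal niches of one cycle (zero-supply resources excluded)."""
    durations = record.phase_durations
    return [
        TemporalNiche(available_resources=avail, duration=float(d))
        for avail, d in zip(record.available_sets, durations)
    ]


def tally_niches(source: Trajectory | Iterable[CycleRecord]) -> NicheTally:
    """Tally distinct niches over a trajectory window or explicit cycle records.

    Niche identity is the available-resource set (durations are summarized,
    not part of identity).  For a :class:`Trajectory` the tallies accumulated
    during the run are used; otherwise records are scanned directly.
    """
    if isinstance(source, Trajectory):
        if not source.niche_counts:
            raise ValueError("trajectory carries no niche tallies (tally_niches=False?)")
        return NicheTally(
            counts=dict(source.niche_counts),
            mean_durations=dict(source.niche_durations),
            n_cycles=source.niche_cycles,
            n_resources=source.n_resources,
        )
    counts: dict[frozenset[int], int] = {}
    total_dur: dict[frozenset[int], float] = {}
    n_cycles = 0
    n_resources = 0
    for rec in source:
        n_cycles += 1
        n_resources = rec.supply.size
        for niche in niches_of_cycle(rec):
            counts[niche.available_resources] = counts.get(niche.available_resources, 0) + 1
            total_dur[niche.available_resources] = (
                total_dur.get(niche.available_resources, 0.0) + niche.duration
            )
    if n_cycles == 0:
        raise ValueError("need at least one cycle record")
    return NicheTally(
        counts=counts,
        mean_durations={k: total_dur[k] / counts[k] for k in counts},
        n_cycles=n_cycles,
        n_resources=n_resources,
    )


def time_on_preferences(
    trajectory: Trajectory,
    species: Sequence[str] | None = None,
) -> np.ndarray:
    """Mean hours per cycle spent on each preference rank, averaged over species.

    Averages the trajectory's accumulated per-species times (final-window
    means) over the surviving species, or over ``species`` if given.  Species
    are weighted equally regardless of abundance.
    """
    if species is None:
        mask = trajectory.survivor_mask
    else:
        wanted = set(species)
        mask = np.array([sid in wanted for sid in trajectory.species_ids])
    if not np.any(mask):
        raise ValueError("no species to average over")
    return trajectory.tau_time[mask].mean(axis=0)


def optimal_allocation(tau: np.ndarray) -> np.ndarray:
    """Growth-rate allocation maximizing sum_k g_k tau_k with |g|_2 = 1.

    ``tau[k]`` is the expected time per cycle spent growing on the k-th
    preference.  Closed form: g* = tau / |tau|_2.
    """
    t = np.asarray(tau, dtype=float)
    if np.any(t < 0):
        raise ValueError("tau must be non-negative")
    norm = np.linalg.norm(t)
    if norm == 0:
        raise ValueError("tau must not be all zero")
    return t / norm


def optimal_strategy_set(tau: np.ndarray, n_resources: int) -> list[OptimalStrategy]:
    """The optimal allocation applied to every preference permutation (N! strategies)."""
    alloc = optimal_allocation(tau)
    if alloc.size != n_resources:
        raise ValueError("tau must have one entry per preference rank")
    strategies = []
    for perm in permutations(range(n_resources)):
        g = np.zeros(n_resources)
        for rank, resource in enumerate(perm):
            g[resource] = alloc[rank]
        strategies.append(OptimalStrategy(preference_order=perm, growth_rates=g))
    return strategies


_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


def simplex_coordinates(vector: np.ndarray, mode: str = "supply") -> np.ndarray:
    """2-D barycentric embedding of a 3-component composition.

    ``mode="supply"`` embeds the (normalized) vector directly; corners are
    single-resource supplies and the centroid is equal supply.
    ``mode="squared-growth"`` embeds g_i^2 / sum g_i^2, a nonlinear map under
    which complete specialization still hits the corners and equal investment
    in all resources (g_i = 1/sqrt(3)) the centroid.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape != (3,) or np.any(v < 0):
        raise ValueError("need a 3-component non-negative vector")
    if mode == "squared-growth":
        v = v**2
    elif mode != "supply":
        raise ValueError("mode must be 'supply' or 'squared-growth'")
    tot = v.sum()
    if tot <= 0:
        raise ValueError("vector must have positive total")
    w = v / tot
    return w @ _CORNERS


def survivor_strategy_distance(
    survivors: Sequence[SpeciesTraits] | np.ndarray,
    strategies: Sequence[OptimalStrategy],
) -> dict:
    """Euclidean distance from each survivor's growth rates to the nearest strategy.

    Returns per-survivor distances plus mean and max summaries.  The distance
    is computed in growth-rate space (indexed by resource), so it is invariant
    under a joint relabeling of resources.
    """
    if len(strategies) == 0:
        raise ValueError("need at least one strategy")
    if len(survivors) == 0:
        raise ValueError("need at least one survivor")
    if isinstance(survivors, np.ndarray):
        gmat = np.atleast_2d(np.asarray(survivors, dtype=float))
    else:
        gmat = np.stack([sp.growth_rates for sp in survivors])
    smat = np.stack([st.growth_rates for st in strategies])
    dists = np.linalg.norm(gmat[:, None, :] - smat[None, :, :], axis=2)
    nearest = dists.min(axis=1)
    return {
        "distances": nearest,
        "nearest_strategy": dists.argmin(axis=1),
        "mean": float(nearest.mean()),
        "max": float(nearest.max()),
    }
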