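"""Serialization of trajectories and down-sampling of long runs."""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CycleRecord, Trajectory

__all__ = [
    "DEFAULT_THINNING",
    "thin_cycles",
    "thin_trajectory",
    "trajectory_to_frame",
    "save_trajectory",
    "records_to_jsonl",
]

#: (start, stop, stride) spans over 1-based cycle numbers: every cycle through
#: 10, every 2nd through 50, every 5th through 200, every 10th through 1000,
#: every 20th through 2000, every 50th through 4000, every 100th through 7000,
#: every 200th through 10^4 and every 500th through 10^6.
DEFAULT_THINNING: tuple[tuple[int, int, int], ...] = (
    (1, 10, 1),
    (10, 50, 2),
    (50, 200, 5),
    (200, 1_000, 10),
    (1_000, 2_000, 20),
    (2_000, 4_000, 50),
    (4_000, 7_000, 100),
    (7_000, 10_000, 200),
    (10_000, 1_000_000, 500),
)


def thin_cycles(
    n_cycles: int,
    schedule: Sequence[tuple[int, int, int]] = DEFAULT_THINNING,
) -> np.ndarray:
    """1-based cycle numbers retained by a (start, stop, stride) schedule."""
    keep: set[int] = set()
    for start, stop, stride in schedule:
        hi = min(stop, n_cycles)
        c = start
        while c <= hi:
            keep.add(c)
            c += stride
    return np.array(sorted(k for k in keep if 1 <= k <= n_cycles), dtype=np.int64)


def thin_trajectory(
    trajectory: Trajectory,
    schedule: Sequence[tuple[int, int, int]] = DEFAULT_THINNING,
) -> Trajectory:
    """Trajectory restricted to the cycles a thinning schedule retains.

    Cycle numbers in the schedule are 1-based; the trajectory's recorded
    cycles are 0-based, so retained cycle number c maps to index c - 1.
    Cycles the trajectory never recorded are simply absent from the result.
    """
    keep_1based = thin_cycles(trajectory.n_cycles, schedule)
    keep = set((keep_1based - 1).tolist())
    mask = np.array([c in keep for c in trajectory.recorded_cycles])
    return replace(
        trajectory,
        recorded_cycles=trajectory.recorded_cycles[mask],
        fractions=trajectory.fractions[mask],
    )


def trajectory_to_frame(trajectory: Trajectory, drop_extinct: bool = True) -> pd.DataFrame:
    """Tidy (cycle, species_id, fraction) frame of the recorded cycles."""
    rows = []
    cycles = np.repeat(trajectory.recorded_cycles, len(trajectory.species_ids))
    species = np.tile(np.array(trajectory.species_ids), trajectory.recorded_cycles.size)
    frac = trajectory.fractions.ravel()
    df = pd.DataFrame({"cycle": cycles, "species_id": species, "fraction": frac})
    if drop_extinct:
        df = df[df["fraction"] > 0.0]
    return df.reset_index(drop=True)


def save_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    trajectory_to_frame(trajectory).to_csv(path, index=False)


def records_to_jsonl(records: Sequence[CycleRecord], path: str | Path) -> None:
    """Cycle event records as JSON lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "cycle": rec.cycle_index,
                        "supply": rec.supply.tolist(),
                        "depletion_times": rec.depletion_times.tolist(),
                        "depletion_order": rec.depletion_order,
                        "phase_boundaries": rec.phase_boundaries.tolist(),
                        "available_sets": [sorted(s) for s in rec.available_sets],
                        "cycle_length": rec.cycle_length,
                    }
                )
                + "\n"
            )
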