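"""Species trait definitions and pool serialization.

A species is defined by a vector of per-resource exponential growth rates
``g_i`` (hr^-1) and a resource-preference order: a permutation of the
resource indices, most preferred first.  A species always consumes its
highest-preference resource that has not yet been depleted.

Resource indices are 0-based throughout the package; the CSV/JSON
serialization uses 1-based resource numbers (``g_1 .. g_N``,
``pref_1 .. pref_N``) as is conventional when writing such tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTraits",
    "rate_order",
    "pool_arrays",
    "pool_to_frame",
    "pool_from_frame",
    "save_pool",
    "load_pool",
]


def rate_order(growth_rates: np.ndarray) -> np.ndarray:
    """Resource indices sorted by descending growth rate (ties -> lower index)."""
    g = np.asarray(growth_rates, dtype=float)
    return np.lexsort((np.arange(g.size), -g)).astype(np.int64)


@dataclass(frozen=True)
class SpeciesTraits:
    """One species: identifier, growth rates (hr^-1), preference permutation.

    ``anomalous`` is derived: True iff the preference order does not sort the
    growth rates in descending order (ties broken by resource index).
    """

    species_id: str
    growth_rates: np.ndarray
    preference_order: np.ndarray
    anomalous: bool = field(init=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.growth_rates, dtype=float)
        pref = np.asarray(self.preference_order, dtype=np.int64)
        if g.ndim != 1 or g.size == 0:
            raise ValueError("growth_rates must be a non-empty 1-D vector")
        if not np.all(np.isfinite(g)) or np.any(g <= 0.0):
            raise ValueError(f"{self.species_id}: growth rates must be positive and finite")
        if sorted(pref.tolist()) != list(range(g.size)):
            raise ValueError(
                f"{self.species_id}: preference_order must be a permutation of 0..{g.size - 1}"
            )
        object.__setattr__(self, "growth_rates", g)
        object.__setattr__(self, "preference_order", pref)
        object.__setattr__(self, "anomalous", not np.array_equal(pref, rate_order(g)))

    @property
    def n_resources(self) -> int:
        return int(self.growth_rates.size)

    def preference_rank(self, resource: int) -> int:
        """0-based rank of ``resource`` in this species' preference order."""
        return int(np.where(self.preference_order == resource)[0][0])


def pool_arrays(pool: Sequence[SpeciesTraits]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack a pool into (growth-rate matrix, preference matrix, id list).

    Growth matrix is (S, R); preference matrix row ``m`` lists resource
    indices in rank order for species ``m``.
    """
    if len(pool) == 0:
        raise ValueError("empty species pool")
    n_res = pool[0].n_resources
    if any(sp.n_resources != n_res for sp in pool):
        raise ValueError("all species must share the same number of resources")
    g = np.stack([sp.growth_rates for sp in pool]).astype(float)
    pref = np.stack([sp.preference_order for sp in pool]).astype(np.int64)
    ids = [sp.species_id for sp in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("species ids must be unique")
    return g, pref, ids


def pool_to_frame(pool: Sequence[SpeciesTraits]) -> pd.DataFrame:
    g, pref, ids = pool_arrays(pool)
    n = g.shape[1]
    data: dict = {"species_id": ids}
    for i in range(n):
        data[f"g_{i + 1}"] = g[:, i]
    for k in range(n):
        data[f"pref_{k + 1}"] = pref[:, k] + 1  # 1-based on disk
    return pd.DataFrame(data)


def pool_from_frame(df: pd.DataFrame) -> list[SpeciesTraits]:
    g_cols = sorted([c for c in df.columns if c.startswith("g_")], key=lambda c: int(c[2:]))
    p_cols = sorted([c for c in df.columns if c.startswith("pref_")], key=lambda c: int(c[5:]))
    if not g_cols or len(g_cols) != len(p_cols):
        raise ValueError("expected matching g_1..g_N and pref_1..pref_N columns")
    return [
        SpeciesTraits(
            species_id=str(row["species_id"]),
            growth_rates=np.array([row[c] for c in g_cols], dtype=float),
            preference_order=np.array([int(row[c]) - 1 for c in p_cols], dtype=np.int64),
        )
        for _, row in df.iterrows()
    ]


def save_pool(pool: Sequence[SpeciesTraits], path: str | Path) -> None:
    """Write a pool as CSV or JSON depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = [
            {
                "species_id": sp.species_id,
                "growth_rates": sp.growth_rates.tolist(),
                "preference_order": (sp.preference_order + 1).tolist(),
            }
            for sp in pool
        ]
        path.write_text(json.dumps(records, indent=1))
    else:
        pool_to_frame(pool).to_csv(path, index=False)


def load_pool(path: str | Path) -> list[SpeciesTraits]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        return [
            SpeciesTraits(
                species_id=str(r["species_id"]),
                growth_rates=np.array(r["growth_rates"], dtype=float),
                preference_order=np.array(r["preference_order"], dtype=np.int64) - 1,
            )
            for r in records
        ]
    return pool_from_frame(pd.read_csv(path))
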