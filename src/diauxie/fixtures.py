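"""Small constructed communities with documented expected outcomes.

These are deterministic fixtures for tests and demos — not samples from the
random pool generator.
"""

from __future__ import annotations

import numpy as np

from .pools import PoolSpec, sample_pool
from .traits import SpeciesTraits

__all__ = ["generate_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "two-species-coexistence",
    "mirror-pair",
    "three-specialists",
    "random-small",
)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def generate_fixtures(kind: str, seed: int = 0) -> list[SpeciesTraits]:
    """Deterministic small communities.

    - ``two-species-coexistence``: two species on two resources with opposed
      preferences; the fast starter depletes its preferred resource first and
      slows down, letting the other catch up — they coexist at a fixed point.
    - ``mirror-pair``: rates swapped across two symmetrically supplied
      resources; by symmetry both persist at equal fractions.
    - ``three-specialists``: rate-ordered specialists, one per resource; on an
      equal three-resource supply all three survive.
    - ``random-small``: a reproducible 8-species, 3-resource random pool.
    """
    if kind == "two-species-coexistence":
        return [
            SpeciesTraits("A", _unit([1.0, 0.30]), np.array([0, 1])),
            SpeciesTraits("B", _unit([0.40, 1.0]), np.array([1, 0])),
        ]
    if kind == "mirror-pair":
        return [
            SpeciesTraits("M1", _unit([0.8, 0.6]), np.array([0, 1])),
            SpeciesTraits("M2", _unit([0.6, 0.8]), np.array([1, 0])),
        ]
    if kind == "three-specialists":
        return [
            SpeciesTraits("S1", _unit([1.0, 0.2, 0.2]), np.array([0, 1, 2])),
            SpeciesTraits("S2", _unit([0.2, 1.0, 0.2]), np.array([1, 0, 2])),
            SpeciesTraits("S3", _unit([0.2, 0.2, 1.0]), np.array([2, 0, 1])),
        ]
    if kind == "random-small":
        return sample_pool(PoolSpec(n_resources=3, n_species=8, seed=seed))
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
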