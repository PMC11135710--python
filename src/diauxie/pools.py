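"""Random species pools under the L2 metabolic trade-off.

Growth-rate vectors are sampled uniformly from the positive orthant of the
unit sphere (``sum_i g_i^2 = 1 hr^-2``): draw a symmetric multivariate
normal, take absolute values, normalize to unit length.  The L2 constraint
(rather than L1) reflects sequential utilization — species never consume two
resources at once, so investment in one resource need not trade off
one-to-one against another.

Preferences are either independent uniform permutations (allowing
"anomalous" species whose preferences do not follow their growth-rate order)
or set to match the descending growth-rate order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .traits import SpeciesTraits, rate_order

__all__ = [
    "PoolSpec",
    "sample_growth_rates",
    "assign_preferences",
    "pool_size",
    "sample_pool",
]


@dataclass(frozen=True)
class PoolSpec:
    n_resources: int
    n_species: int
    constraint: str = "l2"  # "l2" (unit norm) or "none" (uniform(0,1] rates)
    preference_mode: str = "independent-random"  # or "rate-ordered"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_resources < 1:
            raise ValueError("need at least one species and one resource")
        if self.constraint not in ("l2", "none"):
            raise ValueError("constraint must be 'l2' or 'none'")
        if self.preference_mode not in ("independent-random", "rate-ordered"):
            raise ValueError("preference_mode must be 'independent-random' or 'rate-ordered'")


def sample_growth_rates(
    n_resources: int,
    rng: np.random.Generator,
    constraint: str = "l2",
) -> np.ndarray:
    """One growth-rate vector; with the L2 constraint, unit norm exactly."""
    if constraint == "l2":
        g = np.abs(rng.standard_normal(n_resources))
        while not np.any(g > 0):  # measure-zero guard
            g = np.abs(rng.standard_normal(n_resources))
        return g / np.linalg.norm(g)
    if constraint == "none":
        return 1.0 - rng.random(n_resources)  # uniform on (0, 1]
    raise ValueError("constraint must be 'l2' or 'none'")


def assign_preferences(
    growth_rates: np.ndarray,
    mode: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Preference permutation (rank -> resource index)."""
    g = np.asarray(growth_rates, dtype=float)
    if mode == "rate-ordered":
        return rate_order(g)
    if mode == "independent-random":
        if rng is None:
            raise ValueError("independent-random preferences need an rng")
        return rng.permutation(g.size).astype(np.int64)
    raise ValueError("mode must be 'independent-random' or 'rate-ordered'")


def pool_size(
    n_resources: int,
    density_constant: float = 500.0,
    cap: int | None = 5000,
) -> int:
    """Pool size from the constant-density rule rho^dim = const, dim = N - 1.

    The density rho is set so that three resources give a pool of
    ``density_constant`` (default 500) species.  The literal rule explodes
    combinatorially (11,180 species at four resources, ~1.25e8 at seven), so
    a configurable hard cap (default 5000) bounds the result; pass
    ``cap=None`` to disable it.
    """
    if n_resources < 2:
        raise ValueError("the density rule needs at least 2 resources")
    rho = density_constant ** 0.5  # rho^(3-1) = density_constant
    n = int(round(rho ** (n_resources - 1)))
    if cap is not None and n > cap:
        warnings.warn(
            f"pool_size({n_resources}) = {n} capped at {cap}", stacklevel=2
        )
        return cap
    return n


def sample_pool(spec: PoolSpec, rng: np.random.Generator | None = None) -> list[SpeciesTraits]:
    """Sample a reproducible pool of species according to ``spec``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_species)))
    pool = []
    for j in range(spec.n_species):
        g = sample_growth_rates(spec.n_resources, rng, spec.constraint)
        pref = assign_preferences(g, spec.preference_mode, rng)
        pool.append(
            SpeciesTraits(
                species_id=f"sp{j:0{width}d}",
                growth_rates=g,
                preference_order=pref,
            )
        )
    return pool
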