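"""Per-cycle resource supply schedules.

All schedules emit supply vectors on the unit simplex (``s_i >= 0``,
``sum_i s_i = 1``).  The stochastic family is parameterized by the
fluctuation magnitude

    sigma_RS = sqrt( < (s_i - 1/N)^2 > ),

the RMS deviation of supply fractions from equal supply, averaged over
components and cycles.  For three resources the family is a maximum-entropy
density on the simplex,

    p(s)  ∝  exp( -|s - center|^2 / (2 v) ),

a normal centered on equal supply, clipped by s_i > 0, whose shape parameter
``v`` turns negative past the uniform point: v > 0 gives a concave clipped
normal (sigma_RS < sqrt(1/18) ~= 0.2357), |v| -> inf recovers the uniform
simplex, and v < 0 piles mass into the corners up to the single-resource
limit sigma_RS = sqrt(2/9) ~= 0.4714.  The map between v and the realized
sigma_RS is nonlinear once clipping matters, so it is resolved by a
calibration lookup table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "SIGMA_UNIFORM",
    "SIGMA_SINGLE",
    "FluctuationSpec",
    "SeasonalSpec",
    "fluctuation_magnitude",
    "sample_uniform_simplex",
    "single_resource_supply",
    "seasonal_supply",
    "build_supply_sampler",
    "calibrate_shape_parameter",
    "CalibrationTable",
    "ConstantSupply",
    "UniformSimplexSupply",
    "SingleResourceSupply",
    "SeasonalSupply",
    "StochasticSupply",
]

SIGMA_UNIFORM = math.sqrt(1.0 / 18.0)  # uniform-random supply, 3 resources
SIGMA_SINGLE = math.sqrt(2.0 / 9.0)  # a single random resource per cycle

_CORNER_SQ = 2.0 / 3.0  # |corner - center|^2 for 3 resources
# Negative-variance rejection sampling has acceptance ~ 6 v^2 near the
# single-resource limit, so the calibrated family stops at |v| = 0.015
# (sigma_RS ~ 0.45); larger magnitudes are served by the exact
# single-resource sampler at sigma_RS = 0.4714.
_MIN_NEG_V = 0.015
_ANALYTIC_SIGMA = 0.05  # below this clipping is < 1e-9: v = 1.5 sigma^2
_REJECTION_SIGMA = 0.21  # method crossover: >= this, uniform-proposal rejection


def fluctuation_magnitude(samples: np.ndarray) -> float:
    """RMS deviation of supply fractions from equal supply (sigma_RS)."""
    s = np.atleast_2d(np.asarray(samples, dtype=float))
    n = s.shape[1]
    if not np.allclose(s.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each supply vector must sum to 1")
    return float(np.sqrt(np.mean((s - 1.0 / n) ** 2)))


def sample_uniform_simplex(
    n_resources: int, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Uniform (flat-Dirichlet) samples on the simplex."""
    if n_resources < 2:
        raise ValueError("need at least 2 resources")
    out = rng.dirichlet(np.ones(n_resources), size=size)
    return out


def single_resource_supply(
    n_resources: int, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """A uniformly chosen basis vector: one resource carries the whole pulse."""
    if n_resources < 1:
        raise ValueError("need at least 1 resource")
    idx = rng.integers(0, n_resources, size=size)
    out = np.zeros((np.size(idx), n_resources)) if size is not None else np.zeros(n_resources)
    if size is None:
        out[idx] = 1.0
        return out
    out[np.arange(np.size(idx)), idx] = 1.0
    return out


# ---------------------------------------------------------------------------
# seasonal (periodic) schedules


@dataclass(frozen=True)
class SeasonalSpec:
    """Sinusoidal seasonal supply tracing a circle on the simplex.

    ``s_i(k) = 1/3 + A cos(2 pi (k / period - (i - 1)/3))`` with the default
    amplitude A = 0.2969 calibrated so the generated schedule reproduces the
    published three/six/twelve-season supply tables to 3 decimals.
    """

    period: int
    amplitude: float = 0.2969
    phase_offsets: tuple[float, float, float] = (0.0, 1.0 / 3.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        if self.period not in (3, 6, 12):
            raise ValueError("period must be 3, 6 or 12")
        if not 0 < self.amplitude <= 1.0 / 3.0:
            raise ValueError("amplitude must lie in (0, 1/3] to stay on the simplex")


def seasonal_supply(spec: SeasonalSpec, cycle_index: int) -> np.ndarray:
    """Supply vector for growth cycle ``cycle_index`` (0-based)."""
    k = cycle_index % spec.period
    phases = np.asarray(spec.phase_offsets)
    s = 1.0 / 3.0 + spec.amplitude * np.cos(2.0 * np.pi * (k / spec.period - phases))
    return s


def published_seasonal_table():
    """The published per-season supply table (period, cycle, R1..R3), 3 decimals.

    Rows are the reference values the sinusoidal generator is calibrated to
    reproduce; ``cycle`` is 1-based within each period.
    """
    import pandas as pd
    from importlib import resources

    with resources.files(__package__).joinpath("data/seasonal_supply_table.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# calibration of the shape parameter v against realized sigma_RS


@dataclass
class CalibrationTable:
    """Monotone lookup between sigma_RS and the shape parameter v (3 resources)."""

    v_pos: np.ndarray
    sigma_pos: np.ndarray  # increasing with v
    v_neg: np.ndarray  # |v| values, density exponent is positive
    sigma_neg: np.ndarray  # decreasing with |v|

    @property
    def sigma_max(self) -> float:
        """Largest magnitude reachable by the continuous family."""
        return float(self.sigma_neg[0])

    def sigma_to_v(self, sigma: float) -> float:
        """Signed shape parameter for a target fluctuation magnitude."""
        if sigma < _ANALYTIC_SIGMA:
            return 1.5 * sigma**2
        if sigma <= self.sigma_pos[-1]:
            return float(np.interp(sigma, self.sigma_pos, self.v_pos))
        if sigma <= self.sigma_max:
            # sigma_neg is decreasing in |v|; interpolate on the reversed axis
            return -float(np.interp(sigma, self.sigma_neg[::-1], self.v_neg[::-1]))
        raise ValueError(
            f"sigma_RS = {sigma:.4f} is beyond the calibrated family "
            f"(max {self.sigma_max:.4f}); use the single-resource limit 0.4714"
        )


def _sample_clipped_normal(v: float, count: int, rng: np.random.Generator) -> np.ndarray:
    """Exact draws from p(s) ∝ exp(-|s - c|^2 / 2v) on the 3-simplex, v > 0.

    An isotropic 3-D normal projected onto the plane sum(s) = 1 is isotropic
    in that plane with the same per-axis variance, so draws are projected
    normals with boundary rejection.
    """
    out = np.empty((count, 3))
    have = 0
    sd = math.sqrt(v)
    while have < count:
        m = max(2 * (count - have), 1024)
        z = rng.normal(0.0, sd, size=(m, 3))
        s = 1.0 / 3.0 + z - z.mean(axis=1, keepdims=True)
        s = s[np.all(s >= 0.0, axis=1)]
        take = min(count - have, s.shape[0])
        out[have : have + take] = s[:take]
        have += take
    return out


def _sample_rejection(v: float, count: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-proposal rejection draws from the family, either sign of v.

    Acceptance probability is p(s) / max(p(center), p(corner)): for v > 0 the
    density peaks at the center, for v < 0 at the corners.
    """
    out = np.empty((count, 3))
    have = 0
    while have < count:
        m = max(4 * (count - have), 4096)
        s = rng.dirichlet(np.ones(3), size=m)
        d2 = np.sum((s - 1.0 / 3.0) ** 2, axis=1)
        if v > 0:
            p_acc = np.exp(-d2 / (2.0 * v))
        else:
            p_acc = np.exp((d2 - _CORNER_SQ) / (2.0 * abs(v)))
        s = s[rng.random(m) < p_acc]
        take = min(count - have, s.shape[0])
        out[have : have + take] = s[:take]
        have += take
    return out


def _sample_family(v: float, count: int, rng: np.random.Generator) -> np.ndarray:
    if v > 0 and v <= 0.05:
        return _sample_clipped_normal(v, count, rng)
    return _sample_rejection(v, count, rng)


@lru_cache(maxsize=1)
def calibrate_shape_parameter(
    n_grid: int = 41,
    n_draws: int = 200_000,
    seed: int = 20_240,
) -> CalibrationTable:
    """Monte-Carlo lookup table mapping the shape parameter v to sigma_RS.

    Realized magnitudes are estimated with the exact runtime samplers on a
    log-spaced grid for each sign of v, with a fixed calibration seed, and
    inverted by monotone interpolation.  Cached per process.
    """
    rng = np.random.default_rng(seed)
    v_pos = np.geomspace(1e-3, 40.0, n_grid)
    sigma_pos = np.empty(n_grid)
    for j, v in enumerate(v_pos):
        draws = n_draws if v < 5.0 else n_draws // 4
        sigma_pos[j] = fluctuation_magnitude(_sample_family(v, draws, rng))
    v_neg = np.geomspace(_MIN_NEG_V, 40.0, n_grid)
    sigma_neg = np.empty(n_grid)
    for j, v in enumerate(v_neg):
        draws = n_draws // 4 if v < 0.05 else n_draws
        sigma_neg[j] = fluctuation_magnitude(_sample_rejection(-v, draws, rng))
    # enforce monotonicity against residual Monte-Carlo jitter
    sigma_pos = np.maximum.accumulate(sigma_pos)  # increasing in v
    sigma_neg = np.maximum.accumulate(sigma_neg[::-1])[::-1]  # decreasing in |v|
    return CalibrationTable(v_pos, sigma_pos, v_neg, sigma_neg)


# ---------------------------------------------------------------------------
# schedules


@dataclass(frozen=True)
class FluctuationSpec:
    """Target stochastic supply: magnitude sigma_RS on ``n_resources`` = 3.

    The parametric family is defined for three resources (center 1/3).  For
    other resource counts only the uniform-simplex, single-resource and
    constant schedules are available, mirroring how multi-resource experiments
    are run with uniform-random supply.
    """

    sigma_rs: float
    n_resources: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma_rs <= SIGMA_SINGLE + 1e-9:
            raise ValueError("sigma_RS must lie in [0, 0.4714]")


class SupplySchedule:
    """Base class: per-cycle supply vectors on the simplex."""

    n_resources: int
    stochastic: bool

    def sample(self, cycle_index: int, rng: np.random.Generator) -> np.ndarray:
        return self.batch(cycle_index, 1, rng)[0]

    def batch(self, start: int, count: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


class ConstantSupply(SupplySchedule):
    """The same supply vector every cycle (default: equal supply)."""

    stochastic = False

    def __init__(self, n_resources: int = 3, supply: Sequence[float] | None = None):
        self.n_resources = n_resources
        if supply is None:
            self.supply = np.full(n_resources, 1.0 / n_resources)
        else:
            self.supply = np.asarray(supply, dtype=float)
            if self.supply.shape != (n_resources,) or np.any(self.supply < 0):
                raise ValueError("invalid supply vector")
            if abs(self.supply.sum() - 1.0) > 1e-9:
                raise ValueError("supply must sum to 1")

    def batch(self, start, count, rng):
        return np.tile(self.supply, (count, 1))


class UniformSimplexSupply(SupplySchedule):
    """Uniform-random supply on each growth cycle (sigma_RS = 0.2357 for N=3)."""

    stochastic = True

    def __init__(self, n_resources: int = 3):
        self.n_resources = n_resources

    def batch(self, start, count, rng):
        return sample_uniform_simplex(self.n_resources, rng, size=count)


class SingleResourceSupply(SupplySchedule):
    """One uniformly chosen resource per cycle (sigma_RS = 0.4714 for N=3)."""

    stochastic = True

    def __init__(self, n_resources: int = 3):
        self.n_resources = n_resources

    def batch(self, start, count, rng):
        return single_resource_supply(self.n_resources, rng, size=count)


class SeasonalSupply(SupplySchedule):
    """Deterministic sinusoidal seasonal schedule (three resources)."""

    stochastic = False
    n_resources = 3

    def __init__(self, spec: SeasonalSpec | int):
        self.spec = SeasonalSpec(spec) if isinstance(spec, int) else spec

    def batch(self, start, count, rng=None):
        return np.stack([seasonal_supply(self.spec, start + k) for k in range(count)])


class StochasticSupply(SupplySchedule):
    """Maximum-entropy fluctuating supply with target magnitude sigma_RS.

    Sampling method follows the magnitude: below sigma_RS = 0.21 draws come
    from the clipped normal (projected normal plus boundary rejection, with
    the lookup-corrected shape parameter); at 0.21 and above, from a uniform
    simplex proposal thinned by p(s)/max(p(center), p(corner)).  The exact
    uniform point (0.2357) and the single-resource limit (0.4714) use those
    samplers directly.
    """

    stochastic = True
    n_resources = 3

    def __init__(self, spec: FluctuationSpec | float):
        if not isinstance(spec, FluctuationSpec):
            spec = FluctuationSpec(float(spec))
        if spec.n_resources != 3:
            raise ValueError(
                "the sigma_RS family is defined for 3 resources; use "
                "UniformSimplexSupply / SingleResourceSupply for other counts"
            )
        self.spec = spec
        s = spec.sigma_rs
        if s == 0.0:
            self._mode = "constant"
            self.shape_parameter = 0.0
        elif abs(s - SIGMA_UNIFORM) <= 1e-3:
            self._mode = "uniform"
            self.shape_parameter = math.inf
        elif s >= 0.469:
            self._mode = "single"
            self.shape_parameter = -0.0
        else:
            table = calibrate_shape_parameter()
            self.shape_parameter = table.sigma_to_v(s)  # raises beyond the family
            self._mode = "normal" if s < _REJECTION_SIGMA else "rejection"

    def batch(self, start, count, rng):
        mode = self._mode
        if mode == "constant":
            return np.tile(np.full(3, 1.0 / 3.0), (count, 1))
        if mode == "uniform":
            return sample_uniform_simplex(3, rng, size=count)
        if mode == "single":
            return single_resource_supply(3, rng, size=count)
        if mode == "normal":
            return _sample_clipped_normal(self.shape_parameter, count, rng)
        return _sample_rejection(self.shape_parameter, count, rng)


def build_supply_sampler(spec: FluctuationSpec | float) -> StochasticSupply:
    """Schedule for a target fluctuation magnitude (three resources)."""
    return StochasticSupply(spec)
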