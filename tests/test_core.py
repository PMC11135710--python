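import numpy as np
import pytest
from hypothesis import given, strategies as st

from diauxie.core import (
    CommunityState,
    StallError,
    active_resource,
    apply_mortality_and_resupply,
    equal_inoculum,
    population_fractions,
    run_growth_cycle,
    run_serial_dilution,
    solve_phase,
)
from diauxie.fixtures import generate_fixtures
from diauxie.pools import PoolSpec, sample_pool
from diauxie.supply import ConstantSupply
from diauxie.traits import SpeciesTraits

from oracles import ode_cycle


def sp(g, pref, sid="x"):
    return SpeciesTraits(sid, np.array(g, dtype=float), np.array(pref))


class TestActiveResource:
    def test_top_preference_when_present(self):
        s = sp([0.5, 0.4, 0.3], [0, 1, 2])
        assert active_resource(s, {0, 1, 2}) == 0

    def test_rank_order_after_depletion(self):
        s = sp([0.5, 0.4, 0.3], [0, 1, 2])
        assert active_resource(s, {1, 2}) == 1

    def test_only_option(self):
        s = sp([0.5, 0.4, 0.3], [2, 0, 1])
        assert active_resource(s, {1}) == 1

    def test_empty_set_gives_none(self):
        s = sp([0.5, 0.4], [0, 1])
        assert active_resource(s, set()) is None


class TestSolvePhase:
    def test_single_species_closed_form(self):
        # n0 (e^{g t} - 1) = c0  ->  t = ln(1 + c0/n0) / g
        dt, depleted = solve_phase(
            np.array([1 / 9]), np.array([[0.5]]), np.array([0]), np.array([1.0])
        )
        assert dt == pytest.approx(np.log(10.0) / 0.5, rel=1e-12)
        assert depleted == [0]

    def test_two_species_shared_resource_matches_ode(self):
        pool = [sp([1.0], [0], "a"), sp([0.5], [0], "b")]
        n0 = np.array([0.05, 0.05])
        dt, _ = solve_phase(n0, np.array([[1.0], [0.5]]), np.array([0, 0]), np.array([1.0]))
        t_dep, _ = ode_cycle(pool, n0, np.array([1.0]))
        assert dt == pytest.approx(t_dep[0], rel=1e-6)
        # and the root actually solves 0.05(e^t - 1) + 0.05(e^{t/2} - 1) = 1
        assert 0.05 * (np.exp(dt) - 1) + 0.05 * (np.exp(0.5 * dt) - 1) == pytest.approx(1.0, abs=1e-9)

    def test_empty_resource_is_immediate_event(self):
        dt, depleted = solve_phase(
            np.array([0.1, 0.1]),
            np.array([[1.0, 0.5], [0.8, 0.9]]),
            np.array([0, 0]),
            np.array([1.0, 0.0]),
        )
        assert dt > 0 and depleted == [0]
        # a species assigned to an already-empty resource triggers dt = 0
        dt, depleted = solve_phase(
            np.array([0.1, 0.1]),
            np.array([[1.0, 0.5], [0.8, 0.9]]),
            np.array([0, 1]),
            np.array([1.0, 0.0]),
        )
        assert dt == 0.0 and 1 in depleted

    def test_stall_signalled(self):
        with pytest.raises(StallError):
            solve_phase(
                np.array([0.1]), np.array([[1.0, 0.5]]), np.array([-1]), np.array([1.0, 0.5])
            )


class TestGrowthCycle:
    def test_single_species_single_resource(self):
        pool = [sp([0.5], [0], "a")]
        state = CommunityState(np.array([1 / 9]), np.array([1.0]))
        rec, end = run_growth_cycle(state, pool, np.array([1.0]))
        assert rec.cycle_length == pytest.approx(np.log(10.0) / 0.5, rel=1e-12)
        assert end.populations.sum() == pytest.approx(10 / 9, rel=1e-12)

    def test_mass_balance_and_monotone_depletion(self, small_pool, rng):
        supply = rng.dirichlet(np.ones(3))
        n0 = equal_inoculum(len(small_pool))
        state = CommunityState(n0, supply)
        rec, end = run_growth_cycle(state, small_pool, supply)
        gained = end.populations.sum() - n0.sum()
        assert gained == pytest.approx(supply.sum(), abs=1e-9)
        assert np.all(end.populations >= rec.start_populations)
        # depletion order consistent with sorted depletion times
        ts = rec.depletion_times[rec.depletion_order]
        assert np.all(np.diff(ts) >= 0)
        assert rec.cycle_length == pytest.approx(np.max(rec.depletion_times), abs=1e-12)
        # phase durations partition the cycle
        assert rec.phase_durations.sum() == pytest.approx(rec.cycle_length, abs=1e-12)

    def test_zero_supply_resource_depleted_at_t0(self):
        pool = [sp([0.6, 0.4], [0, 1], "a")]
        state = CommunityState(np.array([0.1]), np.array([1.0, 0.0]))
        rec, _ = run_growth_cycle(state, pool, np.array([1.0, 0.0]))
        assert rec.depletion_times[1] == 0.0
        assert rec.depletion_order == [0]
        assert rec.available_sets[0] == frozenset({0})

    def test_event_times_match_ode_integration(self):
        """Event-driven depletion times agree with dense ODE integration."""
        rng = np.random.default_rng(77)
        for _ in range(4):
            S = int(rng.integers(2, 6))
            R = int(rng.integers(2, 5))
            pool = [
                sp(rng.uniform(0.1, 1.2, R), rng.permutation(R), f"s{m}")
                for m in range(S)
            ]
            n0 = rng.uniform(0.02, 0.5, S)
            supply = rng.dirichlet(np.ones(R))
            state = CommunityState(n0, supply)
            rec, end = run_growth_cycle(state, pool, supply)
            t_dep, n_end = ode_cycle(pool, n0, supply)
            assert np.allclose(rec.depletion_times, t_dep, rtol=1e-6)
            assert np.allclose(end.populations, n_end, rtol=1e-6)

    def test_simultaneous_depletion_single_event(self):
        # two identical specialists depleting symmetric supplies at once
        pool = [sp([1.0, 0.1], [0, 1], "a"), sp([0.1, 1.0], [1, 0], "b")]
        state = CommunityState(np.array([0.05, 0.05]), np.array([0.5, 0.5]))
        rec, _ = run_growth_cycle(state, pool, np.array([0.5, 0.5]))
        assert len(rec.available_sets) == 1  # one phase: both deplete together
        assert rec.depletion_times[0] == pytest.approx(rec.depletion_times[1], abs=1e-9)


class TestMortalityAndFractions:
    def test_mortality_divides_by_ten_and_resets_supply(self):
        state = CommunityState(np.array([0.9, 0.2]), np.zeros(2), cycle_index=3)
        nxt = apply_mortality_and_resupply(state, np.array([0.6, 0.4]))
        assert np.allclose(nxt.populations, [0.09, 0.02])
        assert np.allclose(nxt.concentrations, [0.6, 0.4])
        assert nxt.cycle_index == 4

    def test_zero_population_is_fixed_point(self):
        state = CommunityState(np.array([0.0]), np.zeros(1))
        assert apply_mortality_and_resupply(state, np.array([1.0])).populations[0] == 0.0

    def test_fractions(self):
        assert population_fractions(np.array([10 / 9]))[0] == pytest.approx(1.0)
        assert np.allclose(population_fractions(np.array([0.6, 0.4])), [0.6, 0.4])
        # at total biomass 10/9 the fraction equals (9/10) n
        n = np.array([10 / 9 * 0.3, 10 / 9 * 0.7])
        assert np.allclose(population_fractions(n), 0.9 * n)


class TestSerialDilution:
    def test_single_species_converges_to_ten_ninths(self):
        pool = [sp([0.7], [0], "a")]
        traj = run_serial_dilution(pool, ConstantSupply(1, [1.0]), 100, seed=0)
        assert traj.final_biomass == pytest.approx(10 / 9, rel=1e-9)
        assert np.all(traj.fractions[-10:] == 1.0)

    def test_mirror_pair_stays_symmetric(self):
        pool = generate_fixtures("mirror-pair")
        traj = run_serial_dilution(pool, ConstantSupply(2), 300, seed=0, record="all")
        assert np.allclose(traj.fractions, 0.5, atol=1e-9)

    def test_reproducible_given_seed(self, small_pool):
        from diauxie.supply import UniformSimplexSupply

        t1 = run_serial_dilution(small_pool, UniformSimplexSupply(3), 400, seed=9)
        t2 = run_serial_dilution(small_pool, UniformSimplexSupply(3), 400, seed=9)
        assert np.array_equal(t1.fractions, t2.fractions)
        assert t1.survivors == t2.survivors

    def test_extinct_species_recorded_below_threshold(self):
        # a hopeless competitor on one resource dies, and its recorded
        # fraction at the extinction cycle is below the threshold
        pool = [sp([1.0], [0], "fast"), sp([0.2], [0], "slow")]
        traj = run_serial_dilution(
            pool, ConstantSupply(1, [1.0]), 2000, seed=0, record="all",
            extinction_threshold=1e-12,
        )
        assert traj.survivors == ["fast"]
        (loser_cycle,) = [c for s, c in traj.extinctions if s == "slow"]
        assert traj.fractions[loser_cycle, 1] < 1e-12

    def test_fractions_sum_to_one_over_extant(self, small_pool):
        traj = run_serial_dilution(small_pool, ConstantSupply(3), 500, seed=3, record="all")
        assert np.allclose(traj.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_record_cycles_are_consistent_with_block_run(self, small_pool):
        traj = run_serial_dilution(
            small_pool, ConstantSupply(3), 50, seed=1, record="all", record_cycles=[0, 10, 49]
        )
        assert [r.cycle_index for r in traj.records] == [0, 10, 49]
        for rec in traj.records:
            f = population_fractions(rec.end_populations)
            assert np.allclose(f, traj.fractions[rec.cycle_index], atol=1e-12)

    def test_fixed_point_obeys_competitive_exclusion(self):
        """Runs that reach a per-cycle fixed point keep <= N_resources species."""
        for seed in range(4):
            pool = sample_pool(PoolSpec(2, 10, seed=seed))
            traj = run_serial_dilution(
                pool, ConstantSupply(2), 30_000, seed=seed, record="window", record_last=200
            )
            diffs = np.abs(np.diff(traj.fractions[-101:], axis=0)).max()
            if diffs < 1e-10:
                assert len(traj.survivors) <= 2


class TestMassBalanceProperty:
    @given(st.integers(min_value=0, max_value=10_000))
    def test_biomass_gained_equals_total_supply(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(1, 6))
        R = int(rng.integers(1, 5))
        pool = [
            sp(rng.uniform(0.05, 1.5, R), rng.permutation(R), f"s{m}") for m in range(S)
        ]
        n0 = rng.uniform(0.01, 1.0, S)
        supply = rng.dirichlet(np.ones(R))
        state = CommunityState(n0, supply)
        rec, end = run_growth_cycle(state, pool, supply)
        assert end.populations.sum() - n0.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(rec.depletion_times >= 0)
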