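import numpy as np
import pytest

from diauxie.core import CommunityState, run_growth_cycle, run_serial_dilution
from diauxie.fixtures import generate_fixtures
from diauxie.niches import (
    TemporalNiche,
    max_niche_count,
    niches_of_cycle,
    optimal_allocation,
    optimal_strategy_set,
    simplex_coordinates,
    survivor_strategy_distance,
    tally_niches,
    time_on_preferences,
)
from diauxie.supply import ConstantSupply, SingleResourceSupply, UniformSimplexSupply
from diauxie.traits import SpeciesTraits

from oracles import sphere_max_oracle


def sp(g, pref, sid="x"):
    return SpeciesTraits(sid, np.array(g, dtype=float), np.array(pref))


def cycle_record(pool, supply, n0=None):
    n0 = np.full(len(pool), 0.05) if n0 is None else n0
    state = CommunityState(n0, np.asarray(supply, dtype=float))
    rec, _ = run_growth_cycle(state, pool, np.asarray(supply, dtype=float))
    return rec


class TestNichesOfCycle:
    def test_depletion_order_3_1_2(self):
        # a single eater working through preferences R3, R1, R2 realizes the
        # niches {R1,R2,R3} -> {R1,R2} -> {R2}
        rec = cycle_record([sp([0.5, 0.5, 0.5], [2, 0, 1])], [1 / 3, 1 / 3, 1 / 3])
        assert rec.depletion_order == [2, 0, 1]
        sets = [n.available_resources for n in niches_of_cycle(rec)]
        assert sets == [frozenset({0, 1, 2}), frozenset({0, 1}), frozenset({1})]

    def test_depletion_order_1_3_2(self):
        rec = cycle_record([sp([0.5, 0.5, 0.5], [0, 2, 1])], [1 / 3, 1 / 3, 1 / 3])
        sets = [n.available_resources for n in niches_of_cycle(rec)]
        assert sets == [frozenset({0, 1, 2}), frozenset({1, 2}), frozenset({1})]

    def test_single_supplied_resource_single_niche(self):
        rec = cycle_record([sp([0.5, 0.5, 0.5], [0, 1, 2])], [0.0, 1.0, 0.0])
        niches = niches_of_cycle(rec)
        assert [n.available_resources for n in niches] == [frozenset({1})]

    def test_durations_partition_the_cycle(self, small_pool, rng):
        supply = rng.dirichlet(np.ones(3))
        rec = cycle_record(small_pool, supply, n0=np.full(len(small_pool), 0.01))
        niches = niches_of_cycle(rec)
        assert sum(n.duration for n in niches) == pytest.approx(rec.cycle_length, abs=1e-12)

    def test_all_depleted_state_is_not_a_niche(self):
        with pytest.raises(ValueError):
            TemporalNiche(frozenset(), 1.0)


class TestTally:
    def test_fixed_depletion_order_gives_exactly_n_niches(self):
        pool = [sp([0.5, 0.5, 0.5], [2, 0, 1])]
        traj = run_serial_dilution(pool, ConstantSupply(3), 50, seed=0)
        tally = tally_niches(traj)
        assert tally.n_distinct == 3

    def test_bound_holds_under_fluctuating_supply(self, small_pool):
        traj = run_serial_dilution(small_pool, UniformSimplexSupply(3), 2000, seed=4)
        tally = tally_niches(traj)
        assert tally.n_distinct <= max_niche_count(3)
        assert all(len(k) >= 1 for k in tally.counts)

    def test_tally_from_records_matches_trajectory_tally(self, small_pool):
        traj = run_serial_dilution(
            small_pool, UniformSimplexSupply(3), 300, seed=4, record="all",
            record_cycles=range(300),
        )
        from_records = tally_niches(traj.records)
        assert from_records.counts == traj.niche_counts

    def test_max_niche_count_values(self):
        assert max_niche_count(3) == 7
        assert max_niche_count(4) == 15
        assert max_niche_count(5) == 31
        assert round(100 * 23 / max_niche_count(5)) == 74


class TestTimeOnPreferences:
    def test_constant_equal_supply_concentrates_on_top_preference(self):
        # symmetric specialists deplete all resources simultaneously, so all
        # growth happens in the all-resources niche on rank-1 preferences
        pool = generate_fixtures("three-specialists")
        traj = run_serial_dilution(pool, ConstantSupply(3), 300, seed=0)
        tau = time_on_preferences(traj)
        assert tau[0] > 0
        assert tau[1] == pytest.approx(0.0, abs=1e-12)
        assert tau[2] == pytest.approx(0.0, abs=1e-12)

    def test_single_resource_supply_equalizes_ranks(self):
        # at the single-resource limit the favored strategy is the absolute
        # generalist, which spends equal time on each preference rank (each
        # cycle's sole resource lands on a uniformly random rank)
        g = np.full(3, 1 / np.sqrt(3))
        pool = [sp(g, [0, 1, 2], "gen")]
        traj = run_serial_dilution(
            pool, SingleResourceSupply(3), 6000, seed=1, tau_window=0.5
        )
        tau = time_on_preferences(traj)
        assert np.all(np.abs(tau / tau.mean() - 1) < 0.1)

    def test_single_species_single_resource(self):
        pool = [sp([0.8], [0], "a")]
        traj = run_serial_dilution(pool, ConstantSupply(1, [1.0]), 200, seed=0)
        tau = time_on_preferences(traj)
        assert tau[0] == pytest.approx(np.log(10) / 0.8, rel=1e-6)


class TestOptimalStrategies:
    def test_specialist_and_generalist_limits(self):
        assert np.allclose(optimal_allocation([2.5, 0, 0]), [1, 0, 0])
        assert np.allclose(optimal_allocation([1.1, 1.1, 1.1]), np.full(3, 1 / np.sqrt(3)))

    def test_matches_spherical_maximization_oracle(self):
        tau = np.array([0.5, 0.3, 0.2])
        expected = sphere_max_oracle(tau)
        assert np.allclose(optimal_allocation(tau), expected, atol=1e-6)
        assert np.allclose(optimal_allocation(tau), tau / np.linalg.norm(tau), atol=1e-12)

    def test_all_zero_tau_rejected(self):
        with pytest.raises(ValueError):
            optimal_allocation(np.zeros(3))
        with pytest.raises(ValueError):
            optimal_allocation(np.array([-0.1, 0.2, 0.3]))

    @pytest.mark.parametrize("n, expected", [(3, 6), (4, 24)])
    def test_strategy_set_size_and_norms(self, n, expected):
        tau = np.linspace(1.0, 0.2, n)
        strategies = optimal_strategy_set(tau, n)
        assert len(strategies) == expected
        for st in strategies:
            assert np.linalg.norm(st.growth_rates) == pytest.approx(1.0, abs=1e-12)
            # the rank-k allocation sits on the rank-k preferred resource
            alloc = optimal_allocation(tau)
            for rank, resource in enumerate(st.preference_order):
                assert st.growth_rates[resource] == alloc[rank]


class TestSimplexCoordinates:
    def test_centroid_and_corners(self):
        centroid = np.array([0.5, np.sqrt(3) / 6])  # mean of the corners
        assert np.allclose(simplex_coordinates(np.full(3, 1 / 3)), centroid, atol=1e-9)
        assert np.allclose(simplex_coordinates(np.array([1.0, 0, 0])), [0, 0])
        assert np.allclose(
            simplex_coordinates(np.full(3, 1 / np.sqrt(3)), mode="squared-growth"),
            centroid,
            atol=1e-9,
        )
        assert np.allclose(
            simplex_coordinates(np.array([1.0, 0, 0]), mode="squared-growth"), [0, 0]
        )


class TestStrategyDistance:
    def test_zero_at_the_strategies(self):
        tau = np.array([0.6, 0.3, 0.1])
        strategies = optimal_strategy_set(tau, 3)
        gmat = np.stack([st.growth_rates for st in strategies])
        res = survivor_strategy_distance(gmat, strategies)
        assert res["mean"] == 0.0 and res["max"] == 0.0

    def test_invariant_under_resource_relabeling(self, rng):
        tau = np.array([0.6, 0.3, 0.1])
        strategies = optimal_strategy_set(tau, 3)
        g = np.abs(rng.standard_normal((10, 3)))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        before = survivor_strategy_distance(g, strategies)["distances"]
        perm = np.array([2, 0, 1])
        after = survivor_strategy_distance(g[:, perm], strategies)["distances"]
        # the strategy set contains every permutation, so relabeling resources
        # permutes survivors onto other strategies without changing distances
        assert np.allclose(np.sort(before), np.sort(after), atol=1e-12)
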