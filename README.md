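# diauxie

Event-driven simulation and analysis of microbial communities that use
resources **sequentially** (diauxie) under boom-and-bust growth cycles — and
of how that lets far more species coexist than the competitive exclusion
principle would suggest.

## The model

Communities live through discrete growth cycles, as in a serial-dilution
experiment or a seasonal ecosystem.  At the start of a cycle resource
concentrations are set to the supply fractions `s_i` (with `Σ s_i = 1`); each
species `μ` grows exponentially on one resource at a time — whichever
available resource ranks highest in its preference order — at rate `g_μi`
(hr⁻¹), consuming one unit of resource per unit of biomass:

    dn_μ/dt = g_μ,r(t) n_μ,        dc_i/dt = − Σ_{μ eating i} g_μi n_μ .

When every supplied resource is depleted, populations suffer a ten-fold
mortality (`n → n/10`), resources are resupplied, and the next cycle begins.
At the attractor the end-of-cycle biomass is 10/9 and population fractions
equal `(9/10) n_μ`.  Species whose end-of-cycle fraction drops below 10⁻¹²
are removed.

Because growth is piecewise exponential, the package solves each cycle
*exactly* as a sequence of depletion events (sum-of-exponentials root
finding, numba-accelerated) rather than by ODE integration.

Within a cycle resources deplete one after another, so species pass through
*temporal niches* — the nested subsets of still-available resources.  With
`N` resources at most `2^N − 1` distinct niches (and hence coexisting
species) are possible.  The toolkit measures how fluctuating resource supply
(parameterized by the magnitude `σ_RS`, the RMS deviation of supply fractions
from equal supply) multiplies realized niches and drives violations of
competitive exclusion, and predicts the uninvadable "optimal strategies"
`g* ∝ τ` under the metabolic constraint `Σ g_i² = 1 hr⁻²`, where `τ_k` is the
time spent growing on the k-th preference.

## A worked example

```python
import numpy as np
import diauxie as dx

# a 300-species random pool under the metabolic trade-off, three resources
pool = dx.sample_pool(dx.PoolSpec(n_resources=3, n_species=300, seed=0))

# fluctuating resource supply with magnitude sigma_RS = 0.15
schedule = dx.StochasticSupply(0.15)

# the survivor-determination protocol: 5 independent runs, then 3 runs with
# the union of survivors given a ~1000x inoculum head start
report = dx.survivor_protocol(pool, schedule, seed=11,
                              config=dx.ProtocolConfig(n_cycles=10_000))
print(report.n_survivors, report.ce_violation)
# 4 True

traj = dx.run_serial_dilution(report.survivor_traits, schedule, 10_000, seed=1)
print(sorted(dx.tally_niches(traj).counts, key=sorted))
# [frozenset({0}), frozenset({0, 1}), frozenset({0, 1, 2}), frozenset({0, 2}),
#  frozenset({1}), frozenset({1, 2}), frozenset({2})]
print(np.round(dx.time_on_preferences(traj), 2))
# [2.27 0.38 0.18]
```

Four species stably coexist on three resources — a competitive-exclusion
violation made possible by the fluctuating supply.  The tally lists the
distinct temporal niches realized across cycles: here all `2³ − 1 = 7`
nonempty resource subsets occur.  The last line is the mean hours per cycle
the survivors spend growing on their first, second and third preference — at
this moderate fluctuation most growth still happens on top preferences, so
the predicted optimal strategies
(`dx.optimal_strategy_set(report.tau_time, 3)`) lean toward specialists.

The same machinery runs from the shell:

```bash
diauxie pool-gen --n-resources 3 --n-species 300 --seed 42 --out pool.csv
diauxie simulate --pool pool.csv --sigma-rs 0.15 --n-cycles 10000 --seed 1 --out traj.csv
diauxie niches --pool pool.csv --sigma-rs 0.15 --seed 1
```

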