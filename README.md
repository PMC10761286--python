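# bubblesim

Coupled simulation of **disease spreading** (simple contagion) and
**knowledge diffusion** (complex contagion) on synthetic modular temporal
contact networks, for comparing non-pharmaceutical intervention
strategies: preventive quarantines versus *social bubbles* versus
*temporal social bubbles*.

Epidemic control and face-to-face knowledge exchange pull in opposite
directions: quarantines flatten the infection curve but freeze the social
interactions that complex processes (collaboration, expertise transfer,
norm formation) need to spread.  `bubblesim` quantifies this trade-off on
networks whose community strength can be tuned *without changing the
average number of contacts*, so the comparison is about network
organization, not contact volume.

## The model

**Network.**  A population of N = 680 nodes in N_c = 10 bubbles of 68 is
connected by a fresh stochastic-block-model layer every 2 hours, with
within-bubble probability p_intra and between-bubble probability p_inter
tied by a fixed expected link budget (L = 400 links per layer):

    L = Σᵢ nᵢ(nᵢ−1)/2 · p_intra + Σᵢ nᵢ(N−nᵢ)/2 · p_inter

The modularity ratio **p = p_intra/p_inter** sets how self-contained the
bubbles are.  *Temporal clustering* additionally concentrates all
inter-bubble contacts on matched bubble pairs rotating through a
round-robin tournament every d days, with the pair probability boosted so
the expected inter-bubble contact volume is unchanged.

**Disease.**  Non-Markovian SIR: transmission probability β·ω(τ) depends
on the infector's infection age τ (gamma-shaped ω, peak at day 5, zero
from day 10); 80% of cases become symptomatic (log-normal incubation,
median 5.5 d) and are then isolated with probability εI per 2-h step;
isolation triggers tracing of the last 7 days of contacts, each
quarantined with probability εT; confinements last 10 days and cut all
contacts.  β is calibrated so the index case generates R₀ = 1.64
secondary infections on the baseline network.

**Knowledge.**  20 pieces, each seeded on one random node; a node
acquires a piece after K = 8 cumulative contacts with holders (threshold
with memory, never unlearned); exposures accrue every 2 h but
acquisitions activate only at the daily update.  Confined nodes exchange
nothing.

## Worked example

```python
import bubblesim as bs

scenario = bs.Scenario(
    network=bs.NetworkConfig.from_modularity(
        680, 10, 400.0, p=199.0, pairing_period_d=10),
    epi=bs.EpiParams(eps_I=0.1, eps_T=0.0),
    n_runs=50, master_seed=42,
)
ens = bs.run_ensemble(scenario)
ind = ens.indicators
print(f"peak simultaneous infected: {ind.peak_simultaneous_infected_pct:.1f}% of N")
print(f"knowledge milestones (days): one-bubble={ind.t_bubble_knowledge}, "
      f"50%={ind.t_50}, 80%={ind.t_80}")
```

prints

```
peak simultaneous infected: 11.3% of N
knowledge milestones (days): one-bubble=26, 50%=49, 80%=67
```

i.e. with strong bubbles (p = 199) plus 10-day temporal clustering the
epidemic peaks at ~11% of the population — comparable to a quarantine
strategy (εT = 0.1 on an unclustered network peaks at ~9%) — while
knowledge keeps diffusing during the outbreak; the same quarantine
strategy additionally confines ~1 in 5 people who are never infected.
The same object exposes the full ensemble-mean time series
(`ens.mean_frame()`) and per-run results.

The CLI wraps the same functionality:

```bash
bubblesim run --config scenario.yaml --out out/
bubblesim sweep --grid grid.yaml --out out/
bubblesim calibrate-beta --target-r0 1.64
```

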