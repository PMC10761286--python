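# Methods

`bubblesim` simulates two spreading processes running simultaneously on
the same synthetic temporal contact network: a non-Markovian SIR disease
(simple contagion) and a multi-strain threshold-with-memory knowledge
process (complex contagion).  The package exists to compare
non-pharmaceutical intervention strategies — preventive quarantines versus
"social bubbles" (network modularity) versus *temporal* social bubbles
(modularity plus a rotating bubble-pairing schedule) — by their joint
effect on epidemic burden and on the speed of knowledge diffusion.

## Temporal network model

Contacts are a sequence of independent 2-hour layers (12 per day), each a
stochastic block model draw over `N` nodes in `N_c` contiguous clusters
("bubbles") of sizes `n_i`.  Within-cluster pairs link with probability
`p_intra`, between-cluster pairs with `p_inter`.  The two probabilities
are constrained by a fixed expected link count per layer

```
L = Σ_i n_i(n_i−1)/2 · p_intra + Σ_i n_i(N−n_i)/2 · p_inter ,
```

so the modularity ratio `p = p_intra/p_inter` can be tuned without
changing the average contact volume — comparisons across `p` are not
confounded by network density.  The default geometry is `N = 680`, ten
bubbles of 68, `L = 400` links per layer, matching the density of a
well-known smartphone proximity dataset (the Copenhagen Network Study);
the real data are not used.

Layers are i.i.d. across steps: no link persistence, degree correction or
triadic closure.  This is deliberate — modularity is the only structure,
so its effect can be read off directly — but it means the generator does
not emulate the burstiness, daily rhythms or repeated-partner statistics
of real proximity data.  Passing tests therefore validate the mechanism
on networks whose only non-trivial feature is the community structure,
not forecasts for any real population.

**Temporal clustering.**  With a pairing period `d > 0`, inter-bubble
links are concentrated on matched bubble pairs.  Matchings follow the
circle-method round robin: `N_c−1` rounds for even `N_c` (each unordered
bubble pair meets exactly once per tournament; odd `N_c` adds a bye), each
round in force for `d` days, cycling if the horizon outlasts a
tournament.  The matched-pair link probability is boosted to

```
p_pair(a,b) = p_inter · [n_a(N−n_a) + n_b(N−n_b)] / (2 n_a n_b)
```

(`p_inter·(N−n_c)/n_c` for equal sizes), which preserves the expected
inter-bubble link count exactly under a full matching: pairing
*redistributes* inter-bubble contact, it does not remove it.  The
realized intra/inter density ratio (reported by
`metrics.realized_modularity`, computed on the confinement-thinned
layers) stays near the configured `p` throughout a run.  Under pairing
the diagnostic reports the density ratio against all non-bubble pairs;
relative to the active partner alone the concentration factor is
`(N−n_c)/n_c` higher.

## Disease model

Non-Markovian SIR with infection age `τ` (days since own infection,
advanced by 1/12 per step):

* **Transmission.**  A free infected node infects each free susceptible
  contact independently with probability `β·ω(τ)`.  `ω` is a gamma-shaped
  profile with mode at day 5 (shape 6, scale 5/5), normalized to peak 1
  and truncated to zero at day 10.  Only the peak location and the
  10-day support are empirically anchored (COVID-19 generation-interval
  estimates); the exact shape is a modelling choice, and `β` absorbs its
  scale (see calibration).
* **Recovery.**  Infected nodes recover (permanently immune) when
  `τ ≥ 10` days; isolated nodes recover on release.
* **Symptoms.**  80% of infections are symptomatic.  Onset follows a
  log-normal incubation CDF `s(τ)` (median 5.5 days, σ_log = 0.42, in
  line with the COVID-19 literature), applied through the incremental
  hazard `[s(τ+Δ)−s(τ)]/[1−s(τ)]` so onset times have marginal law `s`.
* **Isolation.**  A symptomatic node is detected with probability `εI`
  at each 2-hour update ("probability per unit time", the unit being the
  epidemic update step).  Isolation cuts all contacts for 10 days.
* **Tracing and quarantine.**  On isolation, every distinct partner from
  the node's trailing 7 days of realized contacts is quarantined
  independently with probability `εT` (unless recovered or already
  confined).  Quarantine lasts 10 days; quarantined infected nodes that
  turn symptomatic are promoted to isolation and trigger their own
  tracing.  Confined nodes make no contacts, so they spread neither
  disease nor knowledge, and their absence also thins everyone else's
  contact logs.

Runs start from a fully susceptible population plus one seed infection
with `τ ~ U[0, 10]` — so a substantial fraction of runs (≈50% at
R0 = 1.64, as branching-process theory predicts) go extinct without an
outbreak.  Ensemble means are taken over *all* runs, extinctions
included.

**Calibration.**  `β` is calibrated once by bisection on the empirical
reproduction number (mean offspring of the index case over 3000
simulations per evaluation, common random numbers) on the baseline
network (`p = 5`, `εI = 0.1`, `εT = 0`) to the target R0 = 1.64, giving
the frozen default `β = 0.05346`.  Independent re-estimates at 2000 runs
give 1.60–1.69.

## Knowledge model

20 pieces of knowledge, each initially held by one uniformly chosen node
(independent draws per piece).  A node acquires a piece after
accumulating `K` interactions with nodes holding it — repeated contacts
each count — and never loses it (multi-strain SI).  Exposure counters
advance on every 2-hour layer, but acquisitions and spreading eligibility
refresh only at the daily update, matching the two cadences (epidemic
2 h, knowledge 24 h).  The threshold `K` has no direct empirical
anchor; the default `K = 8` was selected (scan over K at the
bubbles-only scenario, `p = 199`, `εT = 0`) so that within-bubble
diffusion completes on a ~40-day timescale: the day the population mean
reaches one bubble's initial endowment (2 pieces) lands near day 40.
All knowledge milestone
times scale with `K`, so cross-scenario *comparisons* are insensitive to
the exact value; absolute times are not.

## Indicators

* **Peak simultaneous infected** — maximum over time of the
  ensemble-mean curve of active infected + isolated + true-positive
  quarantined (i.e. all currently infected), reported as % of `N`.  The
  peak of the mean curve is used (not the mean of per-run peaks); per-run
  peaks are reported alongside for dispersion.
* **Knowledge milestones** — first day the ensemble-mean knowledge
  reaches `n_pieces/N_c` (= 2), 50% (= 10) and 80% (= 16) of all pieces;
  first-crossing on the daily series, no interpolation.
* **Collateral confinement** — per run, the fraction of nodes confined
  at least once while *never* infected during the run, averaged over all
  runs (×100).  Because extinct runs contribute ≈0, this unconditional
  average is roughly half the value conditional on an outbreak; in the
  quarantine scenario the conditional value is ≈34% while the
  unconditional one is ≈17–20%.
* **Realized modularity** — windowed realized intra/inter density ratio;
  windows with no inter-links report missing, not infinity.

Bootstrap (percentile, 200 resamples over runs) gives 95% CIs for the
peak and collateral indicators.

## Numerical and implementation choices

* Layer sampling draws a binomial count per pair class and then a
  uniform without-replacement index sample decoded through precomputed
  pair tables — exactly the G(n, p) law per class, ~0.15 ms per
  680-node layer.
* Newly infected nodes cannot transmit in the step of their own
  infection (`ω(0) = 0`); when two infectors hit the same susceptible in
  one layer, the attributed infector is chosen uniformly.
* Per-run RNG streams are spawned from the scenario master seed via
  numpy `SeedSequence`, so ensembles are bit-reproducible and runs are
  independent.
* Default horizon 150 days; a run may stop early once no infected remain
  and mean knowledge ≥ 80% of all pieces.  Early-stopped runs are padded
  with their final values when ensembles are averaged (exact for the
  epidemic, a lower bound for knowledge past the stop day; milestones up
  to 80% are unaffected).
* Scenario ensembles in the tests and the acceptance script use 50 runs
  (12–15 for the qualitative sweeps); the source scenarios use 200.
  Ensemble means of the peak indicator at 50 runs move by ~±1–2
  percentage points across master seeds.

## Known limitations

* The unconditional collateral-confinement average is structurally below
  the reported 34% (see above); the package reports the unconditional
  number.
* `ω`, `s` and `K` are calibrated shapes, not measured ones; absolute
  knowledge times and fine curve shapes inherit that uncertainty.
* No waning immunity, vaccination, testing delay, age or household
  structure; no temporally correlated contacts.
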