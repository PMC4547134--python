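# colonynet

Social, spatial and temporal organization of ant colonies from
within-nest interaction logs.

## The problem

Social insects live at high density yet largely escape density-driven
epidemics, supposedly through "collective immunity": the organization
of the colony itself limits how disease can spread. A key question is
whether the workers most likely to carry pathogens into the nest — the
foragers — are socially, spatially, or *temporally* segregated from the
rest of the colony, and whether such segregation would also throttle
the beneficial flow of food. `colonynet` implements the full analysis
chain for answering this from observational data on individually marked
carpenter ants: time-stamped trophallaxis (mouth-to-mouth food
exchange) events, nest exit/entry transits, and grid-resolved movement
tracks recorded during fixed 20-minute observation windows.

It is aimed at behavioural ecologists and network epidemiologists who
have (or want to simulate) event-level interaction logs of a marked
social group.

## What it computes

* **Functional classes** from behavioural history: an ant is an
  *active forager* on nights it crosses the nest boundary, an
  *inactive forager* on later nights once it has ever foraged, a
  *nest worker* until then; the queen is her own class. Once a forager,
  never again a nest worker.
* **Static networks** per colony-night (nodes = ants, one edge per
  interacting dyad, edge attribute = number of discrete events) with
  degree, unnormalized betweenness C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st,
  closeness (reciprocal mean geodesic distance over reachable nodes;
  undefined for isolates) and Burt's constraint
  c_i = Σ_j (p_ij + Σ_q p_iq p_qj)².
* **Group statistics**: tie-corrected Kruskal–Wallis H, Dunn's pairwise
  z post-hocs with Benjamini–Hochberg adjustment, Welch/pooled t-tests.
* **Functional-group networks**: the individual network collapsed onto
  the four classes with total interaction duration as edge weight, the
  canonical census of the 2⁶−1 = 63 possible between-class connection
  patterns, and a null ensemble built from degree-preserving
  double-edge swaps (500 swaps × 100 repetitions per night by default).
* **Ant-time budgets**: person-time exposure denominators (summed
  in-nest seconds per class) turning shared interaction durations into
  per-capita percent time budgets — the same edge weight is a very
  different per-capita risk for a class of 60 than for a lone queen.
* **CTDS movement model**: a continuous-time discrete-space random
  walk on the nest grid with log-linear transition rates
  λ_ij = exp(β·z_ij) (group motility, queen-chamber speed modulation,
  directional queen avoidance), fitted by Newton–Raphson on the
  counting-process likelihood ℓ(β) = Σ [y·βz − τ·e^{βz}], in a
  statsmodels-style `CTDSModel.fit() → CTDSResults.summary()` API,
  plus residence maps and movement-rate contrasts.
* **Temporal spread**: time-respecting reachability over the observed
  contact ordering, seeded resource-spread curves, and an audit of
  whether any time-respecting chain links a just-returned forager to
  the queen.
* **Synthetic colonies**: a generator with class-structured Poisson
  interaction rates, exponential forager sojourns, log-normal event
  durations and CTDS tracks, with known ground truth for every stage.

## Worked example

```bash
colonynet run --scenario paper_like --seed 42 --out out/
```

prints

```
colonynet 0.1.0 run (seed 42, 2203 events, 16 colony-nights)
  static     ok: 16 networks
  stats      ok
  function   ok: 16 empirical subgraphs, 1600 null realizations
  ant_time   ok
  movement   ok: spread index {'nest_worker': 1.0, 'forager': 1.0, 'queen': 0.1587}
  temporal   ok: 2 time-respecting forager->queen chain(s), final spread fraction 0.412
```

Reading: the 2-colony × 8-night synthetic design yields 16 per-night
networks; each is collapsed to a 4-class functional network and
compared against 100 swap-randomized realizations (16 × 100 = 1,600
null subgraphs). The queen's residence covers ~16% of the nest cells
while workers range everywhere, and 2 time-respecting forager→queen
contact chains exist in this realization (the `queen_sequestered`
scenario drives this count to 0). The fitted CTDS coefficients in
`out/ctds_fit.json` recover the generator's truth, e.g.

```
log_rate_forager            -5.445  (se 0.042)   # truth log(1/240) = -5.48
log_rate_nest_worker        -4.781  (se 0.030)   # truth log(1/120) = -4.79
queen_chamber_x_forager     +0.702  (se 0.057)   # truth 0.7
toward_queen                -0.052  (se 0.040)   # truth 0 (no avoidance)
```

and the movement contrasts in `out/movement_contrasts.csv` show nest
workers more mobile overall (t = −12.6, p < 1e-9) while foragers speed
up specifically in the queen's chamber (t = +3.6, p < 0.003).

The same pipeline runs on real logs laid out as `events.csv`,
`transits.csv`, `roster.csv` and optional `tracks.csv` / `grid.json`
(`colonynet run --data DIR`); column schemas are documented in
`colonynet.events`.

## Layout

```
src/colonynet/
  events.py         data model, CSV I/O, classification, presence
  synth.py          synthetic colony generator and scenario presets
  static_nets.py    per-night networks and node metrics
  stats.py          K–W / Dunn / BH / t-tests
  function_nets.py  4-class networks, pattern census, swap null
  ant_time.py       person-time budgets
  movement.py       grid, residence maps, CTDS model and simulator
  temporal.py       time-respecting reachability, spread, queen audit
  pipeline.py       end-to-end orchestration
  cli.py            colonynet synth / run / report
docs/methods.md     model descriptions, parameter choices, limitations
```
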