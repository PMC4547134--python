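# Methods

This note documents the models and conventions implemented in
`colonynet`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and time conventions

All times are seconds from the start of a per-night observation window
(default 1200 s). Intervals are half-open `[t0, t1)`, so interval
arithmetic (presence, overlap, exposure) is unambiguous; an event may
end exactly at the window boundary. A trophallaxis event must last
strictly more than 1 s — the observability threshold of the recording
protocol — and this minimum is enforced at parse time (configurable).
Dyads are stored canonically (lexicographically sorted labels), so
`(B, A)` and `(A, B)` records denote the same edge.

Nest presence is reconstructed from transit logs under the only
self-consistent rule available: directions must alternate per ant, and
the initial state is inferred from the first transit (first `enter` ⇒
the ant started outside; first `exit` ⇒ inside). Ants with no transits
are taken to be inside for the whole window. A transit recorded for
the queen is a hard data error rather than a reclassification, because
the study design never has the queen leave the nest.

`cross_validate` reports events whose participants were outside the
nest during any part of the event; it deliberately does not resolve
such conflicts (truncation vs. dropping is a data-cleaning decision the
caller must own).

## Functional classification

Per colony-night: the queen keeps her class; an ant with ≥ 1 transit
that night is an *active forager*; an ant with a transit on any earlier
night but none tonight is an *inactive forager*; otherwise it is a
*nest worker*. The induced class sequence of any worker matches the
regular pattern `nest_worker* (active|inactive)*` — monotonicity is a
tested invariant.

## Static networks and metrics

Networks are simple undirected graphs built on event *counts* (not
durations); every rostered ant is a node, so isolates are retained.
Conventions on disconnected graphs:

* closeness = reciprocal of the mean geodesic distance over *reachable*
  nodes, computed within components; isolates are undefined (NaN), not
  zero, so they cannot inject a spurious group difference into the
  rank tests;
* betweenness is left unnormalized — downstream comparisons are
  rank-based, so normalization is irrelevant;
* Burt's constraint uses event counts as tie strengths (the only
  strengths available) even though degree is unweighted; a flag
  restores binary ties. Constraint is scale-invariant in the weights,
  exactly 1 for pendant vertices, and 1.125 on the unit triangle.

Betweenness and closeness are verified exactly against a hand-written
all-shortest-paths enumeration on every connected graph with ≤ 6 nodes.

## Group statistics

Kruskal–Wallis uses mid-ranks with the tie correction always applied
(metric data here is tie-heavy); Dunn's z uses the matching tie-adjusted
variance and Benjamini–Hochberg adjustment over all pairs. Pair signs
follow the fixed class order (active forager, inactive forager, nest
worker, queen): z is the first-listed minus second-listed mean rank.
The t-test defaults to the Welch form (a robust default given the
groups' unequal spreads); `equal_var=True` restores the pooled form.

A note on BH: the step-up *adjusted p-value* operator is not
idempotent (e.g. [0.1, 0.6] → [0.2, 0.6] → [0.4, 0.6]); the properties
it does satisfy — domination of the raw values, cap at 1, monotonicity
in the sorted order, permutation equivariance — are what the suite
asserts.

## Functional-group networks and the swap null

Collapsing sums event *durations* by class pair; within-class
durations become self-loops (never for the queen). Pattern
classification uses presence/absence of the 6 possible between-class
edges with threshold weight > 0; self-loops are recorded separately and
excluded from the canonical pattern id, keeping the pattern space
aligned with between-class structure (63 = 2⁶ − 1 nonempty patterns;
the count is always derived by enumeration, never hard-coded).

The null ensemble randomizes the *individual-level* network by
double-edge swaps — (u,v),(x,y) → (u,y),(x,v) — rejecting proposals
that would create self-loops or parallel edges, then collapses and
classifies by the fixed roster. Swaps are counted as *successful*
swaps (default 500 per realization, 100 realizations per night), which
guarantees uniform mixing regardless of rejection rate; a flag switches
to proposal counting for parity with toolkit semantics. Degree
sequences and class memberships are bit-identical before and after
swapping — a tested invariant. Graphs admitting no valid swap (e.g. a
star) are returned unchanged with a `swap_exhausted` warning after a
bounded number of proposals (default 100 × n_swaps).

## Ant-time and percent budgets

A class's ant-time on a night is the summed in-nest seconds of its
members: full windows for nest workers, inactive foragers and the
queen; presence-interval totals for active foragers. For a
between-class dyad both classes are engaged for the event duration;
for a within-class dyad each event occupies two members, so engaged
time is twice the summed duration (configurable off for strict
edge-weight parity). Percentages above 100 due to concurrent events
are reported, not clamped — concurrency is a genuine feature. Total
dyad durations conserve total observed trophallaxis seconds exactly.

Design-arithmetic convention: total observation effort quotes the
20-minute window as 0.33 h (two decimals) before multiplying, the
convention of summary reporting; 76 × 2 × 8 × 0.33 rounds to 401
ant-hours.

## CTDS movement model

Movement is a continuous-time Markov chain over grid cells with
transition rates λ_ij = exp(β·z_ij) to adjacent cells j. The default
covariates encode exactly the three scientific contrasts of interest:

| covariate | meaning | units |
|---|---|---|
| `log_rate_{forager,nest_worker,queen}` | log per-neighbour jump rate (s⁻¹) by movement group | log s⁻¹ |
| `queen_chamber_x_{forager,nest_worker}` | log rate multiplier while sharing the queen's chamber | — |
| `toward_queen` (+ `_x_forager`) | jump-target one cell closer to the queen (attraction > 0, avoidance < 0) | — |

Active and inactive foragers are pooled into one movement group, as
individuals transition between those classes across nights. The exact
covariate set is isolated behind `CTDSSpec`, so an alternative
specification can be swapped in without touching estimation.

Each visit with holding time τ expands into one record per adjacent
cell with outcome 1 for the observed destination; final visits
censored by the window end contribute exposure with no event (ignoring
them would bias rates upward). The Poisson-form log-likelihood
ℓ(β) = Σ [y·βz − τ·e^{βz}] equals the exponential-holding /
multinomial-jump trajectory likelihood up to a β-free constant (tested
numerically against a direct trajectory-likelihood oracle) and is
globally concave, so Newton–Raphson with step halving converges from
any start; the intercept-only MLE has the closed form
(#moves)/(Σ exposure), recovered exactly. Standard errors come from
the observed information. Separation caps estimates at |β| = 30 with a
diagnostic. Non-adjacent observed jumps (tracking gaps) are excluded
rather than interpolated — conservative, and configurable policy can
be added at the record-building step.

Movement contrasts use the *ant* as the statistical unit (nights
pooled), avoiding pseudo-replication across transitions: (a) overall
moves per tracked second, forager vs nest worker; (b) each ant's rate
in the queen's chamber minus elsewhere, contrasted between groups.
Ants never observed in the queen's chamber are excluded from (b) with
a notice.

The nest grid preset has 63 one-cm cells in four chambers
(16+16+16+15) connected in a row by single passage edges, with the
queen's cell in the innermost chamber.

## Temporal networks, spread and the queen audit

Contacts are stamped at event start by default (`rule="end"` available
for sensitivity analysis); transmission is instantaneous with a "≤"
tie rule — a resource acquired at time t can pass through another
contact at the same t, evaluated to a fixpoint within each timestamp so
input order is irrelevant. Earliest-arrival reachability is a single
forward sweep over the sorted contacts; the reached set is always a
subset of the static connected component, and time reversal maps
forward reachability onto "who can reach me" (both tested against an
exhaustive-enumeration oracle).

Spread analysis seeds 20 ants (without replacement, among ants in the
nest at time 0 — a resource cannot be seeded on an absent ant) and
reports the fraction of the network reached on a 100 s grid, averaged
by seed class with equal weight per colony-night.

The queen audit asks, for each active forager and each of its nest
*entry* times t_r, whether any time-respecting chain starting from the
forager at a time ≥ t_r reaches the queen within the window. When the
queen is reachable the audit reports one earliest-arrival witness
chain per (forager, entry) rather than enumerating every chain — the
chain count can grow combinatorially and the scientific question
(segregated or not) depends only on existence; the witness makes a
positive finding checkable by hand.

## Synthetic generator

What it emulates: the study design (2 colonies × 8 nights × 76 ants
with one queen, 1200 s windows), class-structured dyadic interaction,
forager nest trips, and grid movement.

Mechanism and defaults (`paper_like` preset; all chosen a priori from
design arithmetic, with the qualitative contrasts of the study system
as targets):

* forager trips: alternating exponential sojourns, mean 600 s inside /
  300 s outside, so a forager transits at least once in most windows;
* dyadic events: homogeneous Poisson per ant pair with class-pair
  rates (per pair per second) AF/IF–AF/IF 1.5e-4, F–NW 1.0e-4, NW–NW
  3.0e-5, Q–NW 1.5e-5, Q–F 2e-6; with 15 foragers and 60 nest workers
  this puts expected forager degree near 6, nest-worker degree near 4
  and expected queen degree near 1;
* events are thinned to spans when both participants are in the nest
  (dropped, not truncated, if interrupted — configurable), so the
  generator never triggers `cross_validate` flags;
* durations: log-normal with median 30 s, σ = 0.8, truncated below at
  the 1 s threshold and to fit the window;
* tracks: CTDS simulation for 5 foragers, 5 nest workers and the queen
  per colony (the tracked-ant design) with truth
  β = (log 1/240, log 1/120, −8, 0.7, 0, 0, 0) — nest workers most
  mobile in-nest, a near-immobile queen, an e^0.7 forager speed-up in
  the queen's chamber, no directional avoidance;
* reproducibility: one RNG stream per (colony, night, stage), keyed
  from the master seed via `SeedSequence`, so output is independent of
  generation order and byte-identical across runs.

The `queen_sequestered` preset structurally enforces temporal
segregation: queen contacts (nest workers only, rate 6e-5 over the
first 300 s, expected degree ≈ 1) end before any forager's first
possible entry (entries begin after 300 s), so the queen audit is
empty by construction — the generator-level analogue of the empirical
temporal-segregation finding.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: no circadian or within-night
non-stationarity, no task switching within a night, no spatial
correlation between interaction location and the participants' tracks
(events get uniform random cells; tracks are simulated independently
of the transit state), no directed food flow, and no
heavy-tailed individual heterogeneity beyond class structure. One
visible consequence: because the walk is spatially homogeneous within
groups, faster groups cover at least as many cells, so the empirical
pattern of foragers occupying *more* nest area than (faster) nest
workers is not reproduced by the default truth; the residence-map and
spread-index code paths are exercised, but that particular contrast
should not be expected from synthetic data.

## Problem sizes used in the tests

The suite runs the null-ensemble bookkeeping at full study parameters
(16 colony-nights × 100 reps × 500 swaps), the type-I error
calibration at 10,000 simulated null datasets (3 groups × 15), and the
CTDS recovery at 100 replicates of the tracked-ant design (11 ants ×
16 colony-nights ≈ 14,000 records per replicate); the
queen-chamber-modulation power check uses 60 replicates of the same
design. Marginal ±2 SE coverage is assessed pooled across replicates ×
coefficients (nominal 95.4%), with the per-coefficient breakdown
computed alongside; joint per-replicate coverage of 7 coefficients at
2 SE would be ≈ 0.95⁷ ≈ 0.72 and is not a meaningful 93% criterion.

## Known limitations

* The ant-time formula is the direct reading of person-time (summed
  member in-nest seconds); it is isolated in `compute_ant_time` so an
  alternative exposure definition can be swapped in.
* Part-window presence conflicts between event and transit logs are
  reported (`cross_validate`) but not resolved.
* The spread model is reachability-only: no recovery, dose-response,
  or infectiousness decay over chained passages.
* Exact permutation p-values and effect sizes are out of scope; the
  rank tests use asymptotic reference distributions.
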