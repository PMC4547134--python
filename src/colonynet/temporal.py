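"""Time-ordered contact networks, resource spread, queen-risk audit.

A temporal network is the time-sorted list of dyadic contacts (one per
trophallaxis event, stamped at its start time by default).  A resource
seeded on an ant at time t spreads instantaneously along contacts in
nondecreasing time order (a resource acquired at time t may be passed
on through another contact at the same t), which is the time-respecting
path semantics of discrete-snapshot temporal graphs.

The queen-risk audit asks the epidemiologically meaningful question:
after an active forager re-enters the nest, does any time-respecting
contact chain starting from it reach the queen before the window ends?
An empty audit is temporal segregation of the queen from returning
foragers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from colonynet.events import (
    ClassRoster,
    FunctionalClass,
    NestTransitEvent,
    ObservationWindow,
    TrophallaxisEvent,
    ValidationError,
    presence_intervals,
)


@dataclass
class TemporalNetwork:
    """Time-sorted contact sequence for one colony-night."""

    colony: str
    night: int
    contacts: list[tuple[str, str, float]]  # (ant_a, ant_b, t_s), sorted by t
    nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        times = [t for _, _, t in self.contacts]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError("contacts must be sorted by time")
        for a, b, _ in self.contacts:
            self.nodes.add(a)
            self.nodes.add(b)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class SpreadResult:
    """Fraction of the network reached over time from one seeded ant."""

    seed: str
    seed_class: FunctionalClass | None
    grid_times: list[float]
    fraction_reached: list[float]


@dataclass
class RiskPath:
    """A time-respecting contact chain from a returned forager to the queen."""

    forager: str
    return_time_s: float
    chain: list[tuple[str, str, float]]


def build_temporal_network(
    events: Sequence[TrophallaxisEvent],
    rule: str = "start",
    *,
    colony: str | None = None,
    night: int | None = None,
    extra_nodes: Sequence[str] = (),
) -> TemporalNetwork:
    """One contact per event, stamped at its start (default) or end time.

    Sorting is stable: simultaneous contacts keep their input order.
    """
    if rule not in ("start", "end"):
        raise ValueError(f"unknown time-stamp rule {rule!r}")
    if events:
        cn = {(e.colony, e.night) for e in events}
        if len(cn) > 1:
            raise ValidationError("events span multiple colony-nights")
        colony, night = next(iter(cn))
    contacts = [
        (e.ant_a, e.ant_b, e.t_start_s if rule == "start" else e.t_end_s)
        for e in events
    ]
    contacts.sort(key=lambda c: c[2])  # stable
    tnet = TemporalNetwork(colony=colony, night=night, contacts=contacts)
    tnet.nodes.update(extra_nodes)
    return tnet


def earliest_arrival(
    tnet: TemporalNetwork,
    source: str,
    t_from: float = 0.0,
    *,
    witness: bool = False,
) -> dict[str, float] | tuple[dict[str, float], dict[str, tuple]]:
    """Earliest time each ant can be reached from ``source``.

    Single forward sweep over the sorted contacts: a contact at time t
    relays the resource if either endpoint was reached at a time <= t.
    Returns ``{ant: earliest_time}`` for reached ants only (the source
    at ``t_from``).  With ``witness=True`` also returns, per reached
    ant, the contact through which it was first reached (for chain
    reconstruction).
    """
    if source not in tnet.nodes:
        raise ValidationError(f"unknown source ant {source!r}")
    arrival: dict[str, float] = {source: t_from}
    via: dict[str, tuple] = {}
    # group simultaneous contacts and iterate each group to a fixpoint so
    # the "<=" tie rule holds regardless of input order within a timestamp
    i, n = 0, len(tnet.contacts)
    while i < n:
        j = i
        t = tnet.contacts[i][2]
        while j < n and tnet.contacts[j][2] == t:
            j += 1
        group = tnet.contacts[i:j]
        changed = True
        while changed:
            changed = False
            for a, b, tc in group:
                ta = arrival.get(a, math.inf)
                tb = arrival.get(b, math.inf)
                if ta <= tc < tb:
                    arrival[b] = tc
                    via[b] = (a, b, tc)
                    changed = True
                elif tb <= tc < ta:
                    arrival[a] = tc
                    via[a] = (a, b, tc)
                    changed = True
        i = j
    if witness:
        return arrival, via
    return arrival


def _witness_chain(
    via: dict[str, tuple], source: str, target: str
) -> list[tuple[str, str, float]]:
    chain = []
    node = target
    while node != source:
        a, b, t = via[node]
        chain.append((a, b, t))
        node = a if node == b else b
    chain.reverse()
    return chain


def spread_analysis(
    tnet: TemporalNetwork,
    roster: ClassRoster | None = None,
    n_seeds: int = 20,
    interval_s: float = 100.0,
    window_s: float = 1200.0,
    rng: np.random.Generator | int | None = None,
    eligible: Sequence[str] | None = None,
) -> list[SpreadResult]:
    """Seeded resource spread over the observed contact ordering.

    Each of ``n_seeds`` ants (sampled without replacement from
    ``eligible``, by default all nodes) is seeded with a resource at
    time 0; the fraction of the network reached is evaluated on the
    ``interval_s`` grid (0, 100, ..., window).  fraction(0) counts the
    seed itself; fractions are nondecreasing and bounded by 1.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pool = sorted(eligible) if eligible is not None else sorted(tnet.nodes)
    if n_seeds > len(pool):
        raise ValidationError(
            f"cannot draw {n_seeds} seeds from {len(pool)} eligible ants"
        )
    if tnet.n_nodes == 0:
        raise ValidationError("empty temporal network")
    seeds = [pool[i] for i in rng.choice(len(pool), size=n_seeds, replace=False)]
    grid = [g * interval_s for g in range(int(window_s // interval_s) + 1)]
    results = []
    for seed in seeds:
        arrival = earliest_arrival(tnet, seed, 0.0)
        times = sorted(arrival.values())
        fractions = [
            sum(1 for t in times if t <= g) / tnet.n_nodes for g in grid
        ]
        cls = None
        if roster is not None:
            cls = roster.get(tnet.colony, tnet.night, seed)
        results.append(
            SpreadResult(
                seed=seed, seed_class=cls, grid_times=grid,
                fraction_reached=fractions,
            )
        )
    return results


def spread_curves(
    results_by_night: Sequence[tuple[str, int, Sequence[SpreadResult]]],
) -> pd.DataFrame:
    """Mean spread curve per seed class, weighting colony-nights equally.

    Per colony-night the per-seed fractions are first averaged within
    seed class; the class curves are then averaged across nights with
    equal weight, matching curves reported per colony as means over
    nights of observation.
    """
    rows = []
    for colony, night, results in results_by_night:
        per_class: dict[str, list[Sequence[float]]] = {}
        grid = None
        for r in results:
            label = r.seed_class.value if r.seed_class else "all"
            per_class.setdefault(label, []).append(r.fraction_reached)
            grid = r.grid_times
        for label, curves in per_class.items():
            mean = np.mean(np.asarray(curves), axis=0)
            for t, f in zip(grid, mean):
                rows.append(
                    {"colony": colony, "night": night, "seed_class": label,
                     "t_s": t, "fraction": f}
                )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["colony", "seed_class", "t_s"])
        .agg(mean_fraction=("fraction", "mean"), sd=("fraction", "std"))
        .reset_index()
    )
    return agg


def queen_transmission_audit(
    events: Sequence[TrophallaxisEvent],
    transits: Sequence[NestTransitEvent],
    roster: ClassRoster,
    window: ObservationWindow,
    rule: str = "start",
) -> list[RiskPath]:
    """Time-respecting forager-to-queen transmission chains.

    For each active forager and each of its nest *entry* times t_r, the
    audit checks whether any time-respecting contact chain starting
    from the forager at a time >= t_r reaches the queen before the
    window ends; if so it reports one earliest-arrival witness chain.
    An empty list demonstrates temporal segregation of the queen from
    returning foragers.
    """
    colony, night = window.colony, window.night
    classes = roster.classes_for(colony, night)
    queens = [a for a, c in classes.items() if c == FunctionalClass.QUEEN]
    if len(queens) != 1:
        raise ValidationError(f"{colony}/{night}: expected exactly one queen")
    queen = queens[0]
    tnet = build_temporal_network(
        [e for e in events if e.colony == colony and e.night == night],
        rule=rule,
        colony=colony,
        night=night,
        extra_nodes=list(classes),
    )
    paths: list[RiskPath] = []
    for ant, cls in sorted(classes.items()):
        if cls != FunctionalClass.ACTIVE_FORAGER:
            continue
        entries = sorted(
            t.time_s
            for t in transits
            if t.colony == colony and t.night == night and t.ant == ant
            and t.direction == "enter"
        )
        for t_r in entries:
            arrival, via = earliest_arrival(tnet, ant, t_r, witness=True)
            if queen in arrival:
                paths.append(
                    RiskPath(
                        forager=ant,
                        return_time_s=t_r,
                        chain=_witness_chain(via, ant, queen),
                    )
                )
    return paths


def audit_report(paths: Sequence[RiskPath]) -> dict:
    """JSON-serializable audit summary."""
    return {
        "n_chains": len(paths),
        "temporally_segregated": len(paths) == 0,
        "chains": [
            {
                "forager": p.forager,
                "return_time_s": p.return_time_s,
                "contacts": [list(c) for c in p.chain],
            }
            for p in paths
        ],
    }
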