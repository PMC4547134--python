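"""Synthetic colony generator with known ground truth.

Emulates the observational design the analyses assume: two colonies of
~76 individually labeled ants (one queen each) observed over 8 nights
in 20-minute windows, with class-structured interaction rates (foragers
better connected than nest workers, a near-isolated queen), forager
exit/entry sojourns, and grid movement in a 4-chamber 63-cell nest.

Mechanism: forager nest trips are alternating exponential sojourns;
trophallaxis events arise from homogeneous Poisson processes per ant
pair whose rate depends on the pair's realized functional classes that
night, thinned to spans when both participants are in the nest;
durations are log-normal (truncated below at the 1 s observability
threshold); movement tracks come from the CTDS simulator with a known
coefficient vector.  Everything is exactly reproducible from (config,
seed): each colony-night consumes dedicated RNG streams derived from
the master seed by fixed keying, so generation order is irrelevant.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from colonynet.events import (
    CLASS_ORDER,
    ClassRoster,
    FunctionalClass,
    NestTransitEvent,
    ObservationWindow,
    TrophallaxisEvent,
    ValidationError,
    classify_ants,
    presence_intervals,
    write_event_log,
    write_roster,
    write_transit_log,
)
from colonynet.movement import CTDSSpec, GridSpec, MovementTrack, simulate_ctds, write_tracks

SHORT_TO_CLASS = {c.short: c for c in CLASS_ORDER}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TripModel:
    """Alternating exponential sojourns for foragers.

    ``exit_rate`` is the in-nest hazard of leaving (per second),
    ``enter_rate`` the outside hazard of returning.  Foragers may start
    the window outside (``start_inside=False``); ``min_entry_s`` delays
    any first entry until that time (used to construct scenarios with
    late-returning foragers).
    """

    exit_rate: float = 1.0 / 600.0
    enter_rate: float = 1.0 / 300.0
    start_inside: bool = True
    min_entry_s: float = 0.0


def uniform_rates(rate: float) -> dict[tuple[str, str], float]:
    """Equal trophallaxis initiation rate for every class pair."""
    out = {}
    for i, a in enumerate(CLASS_ORDER):
        for b in CLASS_ORDER[i:]:
            if a == b == FunctionalClass.QUEEN:
                continue
            out[(a.short, b.short)] = rate
    return out


@dataclass
class ColonyConfig:
    """Generator configuration; defaults are the paper-like design."""

    colonies: tuple[str, ...] = ("C1", "C2")
    n_nest_workers: int = 60
    n_foragers: int = 15
    nights: int = 8
    window_s: float = 1200.0
    #: trophallaxis initiation rate per ant pair per second, keyed by
    #: unordered class-pair short names, e.g. ("AF", "NW")
    rates: dict[tuple[str, str], float] = field(default_factory=dict)
    duration_mu: float = math.log(30.0)
    duration_sigma: float = 0.8
    trip: TripModel = field(default_factory=TripModel)
    grid: GridSpec = field(default_factory=GridSpec.paper_like)
    beta_true: tuple[float, ...] | None = None
    ctds_spec: CTDSSpec = field(default_factory=CTDSSpec)
    n_tracked_foragers: int = 5
    n_tracked_nest_workers: int = 5
    track_queen: bool = True
    #: if set, queen-pair events may only occur in [0, this time)
    queen_contact_before_s: float | None = None
    min_event_duration_s: float = 1.0
    #: drop (True) or truncate (False) events interrupted by an exit
    drop_interrupted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nest_workers < 0 or self.n_foragers < 0 or self.nights < 1:
            raise ConfigError("counts must be non-negative and nights >= 1")
        if self.duration_sigma <= 0:
            raise ConfigError("duration sigma must be positive")
        for (a, b), r in self.rates.items():
            if a == "Q" and b == "Q":
                raise ConfigError("queen-queen pair rate is meaningless")
            if a not in SHORT_TO_CLASS or b not in SHORT_TO_CLASS:
                raise ConfigError(f"unknown class pair ({a}, {b})")
            if r < 0:
                raise ConfigError("rates must be >= 0")
        if self.beta_true is not None and len(self.beta_true) != self.ctds_spec.n_params:
            raise ConfigError("beta_true length does not match the CTDS spec")

    def rate(self, a: FunctionalClass, b: FunctionalClass) -> float:
        key = (a.short, b.short)
        if key in self.rates:
            return self.rates[key]
        return self.rates.get((b.short, a.short), 0.0)

    @property
    def n_ants(self) -> int:
        return self.n_nest_workers + self.n_foragers + 1


@dataclass
class GroundTruth:
    """Config echo plus the realized per-night class composition."""

    config: dict
    seed: int
    class_counts: dict[str, dict[str, dict[str, int]]]  # colony -> night -> short -> n
    beta_true: tuple[float, ...] | None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


@dataclass
class ColonyData:
    events: list[TrophallaxisEvent]
    transits: list[NestTransitEvent]
    tracks: list[MovementTrack]
    roster: ClassRoster
    roster_base: list[tuple[str, str, bool]]
    ground_truth: GroundTruth
    config: ColonyConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_event_log(self.events, outdir / "events.csv")
        write_transit_log(self.transits, outdir / "transits.csv")
        write_tracks(self.tracks, outdir / "tracks.csv")
        write_roster(self.roster_base, outdir / "roster.csv")
        self.config.grid.to_json(outdir / "grid.json")
        self.ground_truth.to_json(outdir / "ground_truth.json")


def _stream(seed: int, colony_idx: int, night: int, stage: int) -> np.random.Generator:
    """Fixed-keyed RNG stream per colony-night and generation stage."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), colony_idx, night, stage))
    )


def _ant_labels(config: ColonyConfig) -> tuple[str, list[str], list[str]]:
    queen = "Q"
    foragers = [f"F{i:02d}" for i in range(1, config.n_foragers + 1)]
    workers = [f"W{i:02d}" for i in range(1, config.n_nest_workers + 1)]
    return queen, foragers, workers


def _simulate_trips(
    config: ColonyConfig, colony: str, colony_idx: int, foragers: Sequence[str]
) -> list[NestTransitEvent]:
    transits: list[NestTransitEvent] = []
    T = config.window_s
    trip = config.trip
    for night in range(1, config.nights + 1):
        rng = _stream(config.seed, colony_idx, night, 0)
        for ant in foragers:
            inside = trip.start_inside
            t = 0.0
            first_entry_pending = not inside
            while True:
                if inside:
                    if trip.exit_rate <= 0:
                        break
                    t += rng.exponential(1.0 / trip.exit_rate)
                    direction = "exit"
                else:
                    if trip.enter_rate <= 0:
                        break
                    dt = rng.exponential(1.0 / trip.enter_rate)
                    if first_entry_pending and trip.min_entry_s > 0:
                        t = max(t, trip.min_entry_s) + dt
                        first_entry_pending = False
                    else:
                        t += dt
                    direction = "enter"
                if t >= T:
                    break
                transits.append(
                    NestTransitEvent(
                        colony=colony, night=night, ant=ant, time_s=t,
                        direction=direction,
                    )
                )
                inside = not inside
    return transits


def _simulate_events(
    config: ColonyConfig,
    colony: str,
    colony_idx: int,
    roster: ClassRoster,
    presence_by_night: dict[int, dict[str, list[tuple[float, float]]]],
    ants: Sequence[str],
) -> list[TrophallaxisEvent]:
    events: list[TrophallaxisEvent] = []
    T = config.window_s
    cells = config.grid.cells
    pairs = [
        (ants[i], ants[j]) for i in range(len(ants)) for j in range(i + 1, len(ants))
    ]
    for night in range(1, config.nights + 1):
        rng = _stream(config.seed, colony_idx, night, 1)
        classes = roster.classes_for(colony, night)
        presence = presence_by_night[night]
        rates = np.array(
            [config.rate(classes[a], classes[b]) for a, b in pairs]
        )
        # queen-pair processes may be confined to an early sub-window;
        # the Poisson intensity is rate x (allowed span)
        t_maxes = np.array(
            [
                config.queen_contact_before_s
                if (
                    config.queen_contact_before_s is not None
                    and FunctionalClass.QUEEN in (classes[a], classes[b])
                )
                else T
                for a, b in pairs
            ]
        )
        counts = rng.poisson(rates * t_maxes)
        for (a, b), k, t_max in zip(pairs, counts, t_maxes):
            if k == 0:
                continue
            starts = rng.uniform(0.0, t_max, size=k)
            durs = rng.lognormal(config.duration_mu, config.duration_sigma, size=k)
            for t0, d in zip(starts, durs):
                if d <= config.min_event_duration_s:
                    continue
                t1 = t0 + d
                if t1 > t_max:
                    if config.drop_interrupted:
                        continue
                    t1 = t_max
                # both participants must be in the nest for the full span
                ok = all(
                    _covered(t0, t1, presence.get(x, [(0.0, T)])) for x in (a, b)
                )
                if not ok:
                    if config.drop_interrupted:
                        continue
                    continue  # truncation to presence not supported for dyads
                if t1 - t0 <= config.min_event_duration_s:
                    continue
                cell = cells[rng.integers(0, len(cells))]
                events.append(
                    TrophallaxisEvent(
                        colony=colony, night=night, ant_a=a, ant_b=b,
                        t_start_s=float(t0), t_end_s=float(t1), cell=cell,
                    )
                )
    events.sort(key=lambda e: (e.night, e.t_start_s, e.ant_a, e.ant_b))
    return events


def _covered(t0: float, t1: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return any(a <= t0 and t1 <= b for a, b in intervals)


def _simulate_tracks(
    config: ColonyConfig,
    colony: str,
    colony_idx: int,
    foragers: Sequence[str],
    workers: Sequence[str],
    queen: str,
) -> list[MovementTrack]:
    if config.beta_true is None:
        return []
    tracks: list[MovementTrack] = []
    tracked = (
        [(a, "forager") for a in foragers[: config.n_tracked_foragers]]
        + [(a, "nest_worker") for a in workers[: config.n_tracked_nest_workers]]
        + ([(queen, "queen")] if config.track_queen else [])
    )
    cells = config.grid.cells
    for night in range(1, config.nights + 1):
        rng = _stream(config.seed, colony_idx, night, 2)
        for ant, group in tracked:
            if group == "queen" and config.grid.queen_cell is not None:
                start = config.grid.queen_cell
            else:
                start = cells[rng.integers(0, len(cells))]
            tr = simulate_ctds(
                np.asarray(config.beta_true), config.grid, config.window_s,
                start, rng, group=group, spec=config.ctds_spec,
                colony=colony, night=night, ant=ant,
            )
            tracks.append(tr)
    return tracks


def generate_colony(config: ColonyConfig) -> ColonyData:
    """Generate a full synthetic dataset from the configuration.

    Returns events, transits, movement tracks, the (re-derived) class
    roster, the base roster and the ground truth; identical
    (config, seed) give identical output.
    """
    queen, foragers, workers = _ant_labels(config)
    all_events: list[TrophallaxisEvent] = []
    all_transits: list[NestTransitEvent] = []
    all_tracks: list[MovementTrack] = []
    roster = ClassRoster()
    roster_base: list[tuple[str, str, bool]] = []
    class_counts: dict[str, dict[str, dict[str, int]]] = {}
    nights = list(range(1, config.nights + 1))

    for colony_idx, colony in enumerate(config.colonies):
        base = (
            [(colony, queen, True)]
            + [(colony, a, False) for a in foragers + workers]
        )
        roster_base.extend(base)
        transits = _simulate_trips(config, colony, colony_idx, foragers)
        colony_roster = classify_ants(transits, base, nights)
        roster.assignments.update(colony_roster.assignments)

        ants = sorted([queen] + foragers + workers)
        presence_by_night = {
            n: presence_intervals(
                transits, ObservationWindow(colony, n, config.window_s), ants
            )
            for n in nights
        }
        all_transits.extend(transits)
        all_events.extend(
            _simulate_events(
                config, colony, colony_idx, colony_roster, presence_by_night, ants
            )
        )
        all_tracks.extend(
            _simulate_tracks(config, colony, colony_idx, foragers, workers, queen)
        )
        class_counts[colony] = {
            str(n): {
                c.short: len(colony_roster.members(colony, n, c)) for c in CLASS_ORDER
            }
            for n in nights
        }

    gt = GroundTruth(
        config={
            "colonies": list(config.colonies),
            "n_nest_workers": config.n_nest_workers,
            "n_foragers": config.n_foragers,
            "nights": config.nights,
            "window_s": config.window_s,
            "rates": {f"{a}-{b}": r for (a, b), r in config.rates.items()},
            "duration_mu": config.duration_mu,
            "duration_sigma": config.duration_sigma,
        },
        seed=config.seed,
        class_counts=class_counts,
        beta_true=config.beta_true,
    )
    return ColonyData(
        events=all_events,
        transits=all_transits,
        tracks=all_tracks,
        roster=roster,
        roster_base=roster_base,
        ground_truth=gt,
        config=config,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: CTDS truth used by the paper-like presets: nest workers are the most
#: mobile in-nest group, the queen nearly immobile, foragers speed up
#: (e^0.7) when sharing the queen's chamber, and there is no
#: directional queen avoidance.
PAPER_LIKE_BETA: tuple[float, ...] = (
    math.log(1.0 / 240.0),   # log_rate_forager
    math.log(1.0 / 120.0),   # log_rate_nest_worker
    -8.0,                    # log_rate_queen
    0.7,                     # queen_chamber_x_forager
    0.0,                     # queen_chamber_x_nest_worker
    0.0,                     # toward_queen
    0.0,                     # toward_queen_x_forager
)

#: Class-pair trophallaxis rates (events per pair per second) giving the
#: qualitative structure reported for the study colonies: foragers with
#: higher degree than nest workers, queen with expected degree ~ 1.
PAPER_LIKE_RATES: dict[tuple[str, str], float] = {
    ("AF", "AF"): 1.5e-4,
    ("AF", "IF"): 1.5e-4,
    ("IF", "IF"): 1.5e-4,
    ("AF", "NW"): 1.0e-4,
    ("IF", "NW"): 1.0e-4,
    ("NW", "NW"): 3.0e-5,
    ("AF", "Q"): 2.0e-6,
    ("IF", "Q"): 2.0e-6,
    ("NW", "Q"): 1.5e-5,
}

SCENARIOS = ("uniform_null", "forager_hub", "queen_sequestered", "paper_like")


def scenario(name: str, seed: int = 0) -> ColonyConfig:
    """Documented preset configurations.

    * ``paper_like`` — 2 colonies x 8 nights x 76 ants (75 workers of
      which ~20% foragers, plus the queen), 1200 s windows, rates giving
      forager-biased connectivity and a near-isolated queen.
    * ``uniform_null`` — identical rates for every class pair: no social
      structure beyond presence.
    * ``forager_hub`` — exaggerated forager connectivity.
    * ``queen_sequestered`` — queen contacts only nest workers, only
      early in the window, while foragers return late: structurally
      enforces temporal segregation of returning foragers from the
      queen (expected queen degree ~ 1).
    """
    if name == "paper_like":
        return ColonyConfig(
            rates=dict(PAPER_LIKE_RATES), beta_true=PAPER_LIKE_BETA, seed=seed
        )
    if name == "uniform_null":
        return ColonyConfig(
            rates=uniform_rates(6.0e-5), beta_true=PAPER_LIKE_BETA, seed=seed
        )
    if name == "forager_hub":
        rates = dict(PAPER_LIKE_RATES)
        rates[("AF", "AF")] = rates[("AF", "IF")] = rates[("IF", "IF")] = 4.0e-4
        rates[("AF", "NW")] = rates[("IF", "NW")] = 2.5e-4
        return ColonyConfig(rates=rates, beta_true=PAPER_LIKE_BETA, seed=seed)
    if name == "queen_sequestered":
        rates = dict(PAPER_LIKE_RATES)
        rates[("AF", "Q")] = rates[("IF", "Q")] = 0.0
        # queen degree ~ 1: 60 workers x 1200 s x rate ~= 1.1, but queen
        # contacts are confined to the first 300 s, so scale by 4
        rates[("NW", "Q")] = 6.0e-5
        return ColonyConfig(
            rates=rates,
            beta_true=PAPER_LIKE_BETA,
            trip=TripModel(start_inside=False, min_entry_s=300.0),
            queen_contact_before_s=300.0,
            seed=seed,
        )
    raise ConfigError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
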