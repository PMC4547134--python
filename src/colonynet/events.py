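"""Event-log data model, readers/validators, functional classification.

The atomic observations are timed, located, dyadic trophallaxis events
and nest transit (exit/enter) events recorded during fixed observation
windows (20 minutes by default).  All times are seconds from the start
of the window; intervals are half-open ``[t0, t1)``.

Behavioural classification follows the ant's history across nights:

* ``queen`` — the colony's single queen (never transits),
* ``active_forager`` — at least one nest exit/entry this night,
* ``inactive_forager`` — transited on an earlier night but not tonight,
* ``nest_worker`` — never observed to leave the nest up to and
  including this night.

Once an ant has been seen foraging it can never revert to nest worker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 1200.0
MIN_EVENT_DURATION_S = 1.0


class ColonyDataError(ValueError):
    """Base class for malformed colony data."""


class SchemaError(ColonyDataError):
    """A required column is missing or a file cannot be parsed."""


class ValidationError(ColonyDataError):
    """One or more rows violate an invariant.

    Attributes
    ----------
    problems : list of (row_index, message)
        Zero-based positions of the offending rows in the input table.
    """

    def __init__(self, message: str, problems: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.problems = problems or []


class FunctionalClass(str, Enum):
    """Behavioural class of an ant on a given night."""

    ACTIVE_FORAGER = "active_forager"
    INACTIVE_FORAGER = "inactive_forager"
    NEST_WORKER = "nest_worker"
    QUEEN = "queen"

    @property
    def short(self) -> str:
        return _SHORT[self]


_SHORT = {
    FunctionalClass.ACTIVE_FORAGER: "AF",
    FunctionalClass.INACTIVE_FORAGER: "IF",
    FunctionalClass.NEST_WORKER: "NW",
    FunctionalClass.QUEEN: "Q",
}

#: Fixed reporting order for the four classes (used for pair signs,
#: canonical pattern ids and table layouts).
CLASS_ORDER: tuple[FunctionalClass, ...] = (
    FunctionalClass.ACTIVE_FORAGER,
    FunctionalClass.INACTIVE_FORAGER,
    FunctionalClass.NEST_WORKER,
    FunctionalClass.QUEEN,
)

WORKER_CLASSES: tuple[FunctionalClass, ...] = (
    FunctionalClass.ACTIVE_FORAGER,
    FunctionalClass.INACTIVE_FORAGER,
    FunctionalClass.NEST_WORKER,
)


@dataclass(frozen=True)
class AntID:
    """An individually labeled ant; labels are unique within a colony."""

    colony: str
    label: str

    def __post_init__(self) -> None:
        if not self.colony or not self.label:
            raise ValidationError("AntID colony and label must be non-empty")


@dataclass(frozen=True)
class ObservationWindow:
    """One colony-night observation window."""

    colony: str
    night: int
    duration_s: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("window duration must be positive")
        if self.night < 1:
            raise ValidationError("nights are numbered from 1")


@dataclass(frozen=True)
class TrophallaxisEvent:
    """One dyadic oral-exchange event.

    The dyad is stored canonically: ``ant_a <= ant_b`` lexicographically,
    so ``(B, A)`` and ``(A, B)`` records are the same event.
    """

    colony: str
    night: int
    ant_a: str
    ant_b: str
    t_start_s: float
    t_end_s: float
    cell: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.ant_a == self.ant_b:
            raise ValidationError("trophallaxis requires two distinct ants")
        if self.ant_a > self.ant_b:  # canonicalize dyad order
            a, b = self.ant_b, self.ant_a
            object.__setattr__(self, "ant_a", a)
            object.__setattr__(self, "ant_b", b)
        if not (0 <= self.t_start_s < self.t_end_s):
            raise ValidationError(
                f"invalid event interval [{self.t_start_s}, {self.t_end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    @property
    def dyad(self) -> tuple[str, str]:
        return (self.ant_a, self.ant_b)


@dataclass(frozen=True)
class NestTransitEvent:
    """A nest boundary crossing: ``direction`` is ``exit`` or ``enter``."""

    colony: str
    night: int
    ant: str
    time_s: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("exit", "enter"):
            raise ValidationError(f"unknown transit direction {self.direction!r}")
        if self.time_s < 0:
            raise ValidationError("transit time must be >= 0")


@dataclass
class ClassRoster:
    """Per colony-night functional class of every ant.

    ``assignments`` maps ``(colony, night, ant)`` to a
    :class:`FunctionalClass`.
    """

    assignments: dict[tuple[str, int, str], FunctionalClass] = field(
        default_factory=dict
    )

    def get(self, colony: str, night: int, ant: str) -> FunctionalClass:
        return self.assignments[(colony, night, ant)]

    def classes_for(self, colony: str, night: int) -> dict[str, FunctionalClass]:
        return {
            ant: cls
            for (c, n, ant), cls in self.assignments.items()
            if c == colony and n == night
        }

    def members(
        self, colony: str, night: int, cls: FunctionalClass
    ) -> list[str]:
        return sorted(
            ant for ant, c in self.classes_for(colony, night).items() if c == cls
        )

    def colony_nights(self) -> list[tuple[str, int]]:
        return sorted({(c, n) for (c, n, _) in self.assignments})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"colony": c, "night": n, "ant": a, "functional_class": cls.value}
            for (c, n, a), cls in sorted(self.assignments.items())
        ]
        return pd.DataFrame(
            rows, columns=["colony", "night", "ant", "functional_class"]
        )


# ---------------------------------------------------------------------------
# Readers / writers (CSV dialect: UTF-8, comma, header row)
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "colony",
    "night",
    "ant_a",
    "ant_b",
    "t_start_s",
    "t_end_s",
    "cell_row",
    "cell_col",
]
TRANSIT_COLUMNS = ["colony", "night", "ant", "time_s", "direction"]
ROSTER_COLUMNS = ["colony", "ant", "is_queen"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_event_log(
    path,
    *,
    window_s: float = DEFAULT_WINDOW_S,
    min_duration_s: float = MIN_EVENT_DURATION_S,
    errors: str = "raise",
) -> list[TrophallaxisEvent]:
    """Read and validate a trophallaxis event log.

    Rows whose interval is invalid, exceeds the window, or whose
    duration is not strictly greater than ``min_duration_s`` are
    rejected with their (zero-based) row index.  With ``errors="raise"``
    any rejection aborts the read; with ``errors="skip"`` offending rows
    are dropped and logged.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, EVENT_COLUMNS[:6], path)
    has_cell = "cell_row" in df.columns and "cell_col" in df.columns

    events: list[TrophallaxisEvent] = []
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        t0, t1 = float(row.t_start_s), float(row.t_end_s)
        msg = None
        if str(row.ant_a) == str(row.ant_b):
            msg = "self-interaction"
        elif t1 <= t0:
            msg = f"t_end ({t1}) <= t_start ({t0})"
        elif t0 < 0 or t1 > window_s:
            msg = f"interval [{t0}, {t1}) outside window [0, {window_s}]"
        elif t1 - t0 <= min_duration_s:
            msg = f"duration {t1 - t0:.3g} s not > {min_duration_s} s threshold"
        if msg is not None:
            problems.append((i, msg))
            continue
        cell = None
        if has_cell and pd.notna(row.cell_row) and pd.notna(row.cell_col):
            cell = (int(row.cell_row), int(row.cell_col))
        events.append(
            TrophallaxisEvent(
                colony=str(row.colony),
                night=int(row.night),
                ant_a=str(row.ant_a),
                ant_b=str(row.ant_b),
                t_start_s=t0,
                t_end_s=t1,
                cell=cell,
            )
        )
    if problems:
        if errors == "raise":
            detail = "; ".join(f"row {i}: {m}" for i, m in problems[:10])
            raise ValidationError(
                f"{path}: {len(problems)} invalid row(s): {detail}", problems
            )
        for i, m in problems:
            logger.warning("%s: skipped row %d: %s", path, i, m)
    return events


def write_event_log(events: Iterable[TrophallaxisEvent], path) -> None:
    rows = [
        {
            "colony": e.colony,
            "night": e.night,
            "ant_a": e.ant_a,
            "ant_b": e.ant_b,
            "t_start_s": e.t_start_s,
            "t_end_s": e.t_end_s,
            "cell_row": e.cell[0] if e.cell else "",
            "cell_col": e.cell[1] if e.cell else "",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_transit_log(
    path, *, window_s: float = DEFAULT_WINDOW_S
) -> list[NestTransitEvent]:
    """Read nest transits; validates times and alternating directions."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRANSIT_COLUMNS, path)
    transits = [
        NestTransitEvent(
            colony=str(r.colony),
            night=int(r.night),
            ant=str(r.ant),
            time_s=float(r.time_s),
            direction=str(r.direction),
        )
        for r in df.itertuples(index=False)
    ]
    for t in transits:
        if t.time_s > window_s:
            raise ValidationError(f"transit at {t.time_s} s beyond window {window_s} s")
    validate_transits(transits)
    return transits


def write_transit_log(transits: Iterable[NestTransitEvent], path) -> None:
    rows = [
        {
            "colony": t.colony,
            "night": t.night,
            "ant": t.ant,
            "time_s": t.time_s,
            "direction": t.direction,
        }
        for t in transits
    ]
    pd.DataFrame(rows, columns=TRANSIT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_roster(path) -> list[tuple[str, str, bool]]:
    """Read the base roster: one row per ant, exactly one queen per colony."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ROSTER_COLUMNS, path)
    roster = [
        (str(r.colony), str(r.ant), bool(r.is_queen))
        for r in df.itertuples(index=False)
    ]
    _check_one_queen(roster)
    return roster


def write_roster(roster: Iterable[tuple[str, str, bool]], path) -> None:
    rows = [{"colony": c, "ant": a, "is_queen": int(q)} for c, a, q in roster]
    pd.DataFrame(rows, columns=ROSTER_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def _check_one_queen(roster: Sequence[tuple[str, str, bool]]) -> None:
    by_colony: dict[str, int] = {}
    for colony, _, is_queen in roster:
        by_colony.setdefault(colony, 0)
        if is_queen:
            by_colony[colony] += 1
    for colony, n in by_colony.items():
        if n != 1:
            raise ValidationError(
                f"colony {colony!r} must have exactly one queen, found {n}"
            )


# ---------------------------------------------------------------------------
# Transit validation, classification, presence
# ---------------------------------------------------------------------------


def _transits_by_ant_night(
    transits: Iterable[NestTransitEvent],
) -> dict[tuple[str, int, str], list[NestTransitEvent]]:
    grouped: dict[tuple[str, int, str], list[NestTransitEvent]] = {}
    for t in transits:
        grouped.setdefault((t.colony, t.night, t.ant), []).append(t)
    for seq in grouped.values():
        seq.sort(key=lambda t: t.time_s)
    return grouped


def validate_transits(transits: Iterable[NestTransitEvent]) -> None:
    """Check strictly increasing times and alternating directions per ant."""
    for (colony, night, ant), seq in _transits_by_ant_night(transits).items():
        for prev, cur in zip(seq, seq[1:]):
            if cur.time_s <= prev.time_s:
                raise ValidationError(
                    f"{colony}/{night}/{ant}: transit times not strictly increasing"
                )
            if cur.direction == prev.direction:
                raise ValidationError(
                    f"{colony}/{night}/{ant}: consecutive {cur.direction!r} transits"
                )


def classify_ants(
    transits: Sequence[NestTransitEvent],
    roster_base: Sequence[tuple[str, str, bool]],
    nights: Sequence[int],
) -> ClassRoster:
    """Assign each ant a functional class on every night.

    The queen keeps her own class; a transit logged for the queen is a
    hard data error.  Any other ant is an active forager on nights with
    at least one transit, an inactive forager on later transit-free
    nights once it has ever foraged, and a nest worker before its first
    observed foraging trip.
    """
    _check_one_queen(roster_base)
    validate_transits(transits)
    queens = {c: a for c, a, q in roster_base if q}
    grouped = _transits_by_ant_night(transits)
    for (colony, night, ant) in grouped:
        if queens.get(colony) == ant:
            raise ValidationError(
                f"queen {ant!r} of colony {colony!r} has a transit on night {night}"
            )

    roster = ClassRoster()
    for colony, ant, is_queen in roster_base:
        if is_queen:
            for night in nights:
                roster.assignments[(colony, night, ant)] = FunctionalClass.QUEEN
            continue
        has_foraged = False
        for night in sorted(nights):
            if (colony, night, ant) in grouped:
                cls = FunctionalClass.ACTIVE_FORAGER
                has_foraged = True
            elif has_foraged:
                cls = FunctionalClass.INACTIVE_FORAGER
            else:
                cls = FunctionalClass.NEST_WORKER
            roster.assignments[(colony, night, ant)] = cls
    return roster


def presence_intervals(
    transits: Sequence[NestTransitEvent],
    window: ObservationWindow,
    ants: Iterable[str] | None = None,
) -> dict[str, list[tuple[float, float]]]:
    """In-nest presence intervals ``[t0, t1)`` per ant for one colony-night.

    The initial state is inferred from the first transit: an ant whose
    first transit is ``enter`` starts the window outside; one whose
    first transit is ``exit`` starts inside.  Ants listed in ``ants``
    with no transits are present for the full window.
    """
    relevant = [
        t for t in transits if t.colony == window.colony and t.night == window.night
    ]
    validate_transits(relevant)
    grouped = _transits_by_ant_night(relevant)
    T = window.duration_s

    presence: dict[str, list[tuple[float, float]]] = {}
    for (_, _, ant), seq in grouped.items():
        inside = seq[0].direction == "exit"  # first event leaves => started inside
        t_prev = 0.0
        intervals: list[tuple[float, float]] = []
        for t in seq:
            if inside and t.time_s > t_prev:
                intervals.append((t_prev, t.time_s))
            inside = t.direction == "enter"
            t_prev = t.time_s
        if inside and t_prev < T:
            intervals.append((t_prev, T))
        presence[ant] = intervals
    if ants is not None:
        for ant in ants:
            presence.setdefault(ant, [(0.0, T)])
    return presence


def presence_seconds(intervals: Sequence[tuple[float, float]]) -> float:
    return sum(t1 - t0 for t0, t1 in intervals)


def _interval_overlap(
    a0: float, a1: float, intervals: Sequence[tuple[float, float]]
) -> float:
    return sum(max(0.0, min(a1, t1) - max(a0, t0)) for t0, t1 in intervals)


def cross_validate(
    events: Sequence[TrophallaxisEvent],
    presence: Mapping[str, Sequence[tuple[float, float]]],
    window: ObservationWindow,
) -> list[dict]:
    """Flag events whose participants are outside the nest at any point.

    Returns a report (list of dicts) with the event, the absent ant and
    the number of seconds of the event spent outside; an empty list
    means the logs are mutually consistent.  Report-only: conflicting
    events are not modified or dropped.
    """
    report: list[dict] = []
    for e in events:
        if e.colony != window.colony or e.night != window.night:
            raise ValidationError("event does not belong to the validated window")
        for ant in e.dyad:
            inside = _interval_overlap(
                e.t_start_s, e.t_end_s, presence.get(ant, [(0.0, window.duration_s)])
            )
            outside = e.duration_s - inside
            if outside > 1e-9:
                report.append(
                    {"event": e, "ant": ant, "outside_overlap_s": outside}
                )
    return report
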