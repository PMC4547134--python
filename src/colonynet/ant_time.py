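"""Person-time ("ant-time") exposure and percent time-budget accounting.

The same total interaction duration between two classes represents very
different per-capita engagement for each class, because classes differ
in size and active foragers spend variable amounts of time in the nest.
Ant-time is the epidemiological person-time denominator: the summed
in-nest seconds of a class's members over the window.  The percent
time-budget of a class dyad is 100 x (engaged seconds) / (class
ant-time), where within-class dyads count each event twice (both
participants are engaged).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from colonynet.events import (
    CLASS_ORDER,
    WORKER_CLASSES,
    ClassRoster,
    FunctionalClass,
    ObservationWindow,
    TrophallaxisEvent,
    ValidationError,
    presence_seconds,
)
from colonynet.function_nets import BETWEEN_CLASS_EDGES, _class_pair


def design_ant_hours(
    n_ants: int,
    n_colonies: int,
    n_nights: int,
    window_s: float = 1200.0,
    *,
    hours_precision: int = 2,
) -> float:
    """Total observation effort, in ant-hours, from the study design.

    The per-window duration is quoted in hours at ``hours_precision``
    decimal places before multiplying, matching the convention of
    summary reporting (a 20-minute window is quoted as 0.33 h).
    """
    hours_per_window = round(window_s / 3600.0, hours_precision)
    return n_ants * n_colonies * n_nights * hours_per_window


def compute_ant_time(
    roster: ClassRoster,
    presence: Mapping[str, Sequence[tuple[float, float]]],
    window: ObservationWindow,
) -> dict[FunctionalClass, float]:
    """Class-level ant-time (summed member in-nest seconds) for one night.

    Nest workers, inactive foragers and the queen contribute full
    windows; active foragers contribute their presence-interval totals.
    Every rostered ant must have a presence record.
    """
    classes = roster.classes_for(window.colony, window.night)
    out: dict[FunctionalClass, float] = {c: 0.0 for c in CLASS_ORDER}
    for ant, cls in classes.items():
        if ant not in presence:
            raise ValidationError(
                f"ant {ant!r} in roster has no presence record"
            )
        out[cls] += presence_seconds(presence[ant])
    return out


def dyad_durations(
    events: Sequence[TrophallaxisEvent], roster: ClassRoster
) -> dict[tuple[FunctionalClass, FunctionalClass], float]:
    """Summed event durations per unordered class pair (incl. self-pairs).

    Conserves time exactly: the values sum to the total observed
    trophallaxis seconds.
    """
    durations: dict[tuple[FunctionalClass, FunctionalClass], float] = {}
    for a, b in BETWEEN_CLASS_EDGES:
        durations[(a, b)] = 0.0
    for c in WORKER_CLASSES:
        durations[(c, c)] = 0.0
    for e in events:
        classes = roster.classes_for(e.colony, e.night)
        try:
            ca, cb = classes[e.ant_a], classes[e.ant_b]
        except KeyError as err:
            raise ValidationError(f"unclassified participant {err}")
        durations[_class_pair(ca, cb)] += e.duration_s
    return durations


def percent_budget(
    durations: Mapping[tuple[FunctionalClass, FunctionalClass], float],
    ant_time: Mapping[FunctionalClass, float],
    *,
    double_within: bool = True,
) -> pd.DataFrame:
    """Percent of each class's time budget engaged per dyad.

    For a between-class dyad (A, B) both classes are engaged for the
    full event duration, so ``pct_of_A = 100 * duration / ant_time_A``
    and symmetrically for B.  For a within-class dyad each event
    occupies two members, so the engaged time is twice the summed
    duration (``double_within=False`` restores strict edge-weight
    parity).  A positive duration with a zero denominator is an error;
    percentages above 100 (concurrent engagement) are reported as-is.
    """
    rows = []
    for (a, b), dur in durations.items():
        if a == b:
            engaged = (2.0 if double_within else 1.0) * dur
            pcts = {a: _pct(engaged, ant_time.get(a, 0.0), a)}
        else:
            pcts = {
                a: _pct(dur, ant_time.get(a, 0.0), a),
                b: _pct(dur, ant_time.get(b, 0.0), b),
            }
        rows.append(
            {
                "class_a": a.short,
                "class_b": b.short,
                "duration_s": dur,
                "pct_of_a": pcts[a],
                "pct_of_b": pcts[b] if b in pcts else pcts[a],
            }
        )
    rows.sort(key=lambda r: (r["class_a"], r["class_b"]))
    return pd.DataFrame(
        rows, columns=["class_a", "class_b", "duration_s", "pct_of_a", "pct_of_b"]
    )


def _pct(engaged_s: float, ant_time_s: float, cls: FunctionalClass) -> float:
    if engaged_s == 0.0:
        return 0.0
    if ant_time_s <= 0.0:
        raise ValidationError(
            f"class {cls.value} has engagement but zero ant-time"
        )
    return 100.0 * engaged_s / ant_time_s


def nightly_budget_table(
    per_night: Sequence[tuple[str, int, pd.DataFrame]]
) -> pd.DataFrame:
    """Stack per-night budgets and aggregate mean +/- sd across nights.

    ``per_night`` holds (colony, night, percent_budget frame) triples.
    Returns one row per (colony, dyad) with mean and sd of the two
    per-class percentages over nights.
    """
    frames = []
    for colony, night, df in per_night:
        d = df.copy()
        d.insert(0, "colony", colony)
        d.insert(1, "night", night)
        frames.append(d)
    stacked = pd.concat(frames, ignore_index=True)
    agg = (
        stacked.groupby(["colony", "class_a", "class_b"])
        .agg(
            mean_pct_of_a=("pct_of_a", "mean"),
            sd_pct_of_a=("pct_of_a", "std"),
            mean_pct_of_b=("pct_of_b", "mean"),
            sd_pct_of_b=("pct_of_b", "std"),
            mean_duration_s=("duration_s", "mean"),
        )
        .reset_index()
    )
    return agg
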