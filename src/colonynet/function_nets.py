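"""Functional-group (4-node) networks, pattern census, rewiring null.

Each colony-night's individual network collapses onto the four
behavioural classes; edge weights are total interaction durations in
seconds, with self-loops allowed for the worker classes (never the
queen).  A *pattern* (network subgraph) is the presence/absence profile
of the six possible between-class edges, identified by a canonical
string such as ``"2:AF-IF|IF-NW"``; worker self-loops are recorded
separately and do not enter the pattern id.

The null model randomizes the individual-level network by repeated
double-edge swaps — replacing edges (u,v),(x,y) with (u,y),(x,v) —
which preserve every ant's degree and each class's membership, then
collapses and classifies each randomized realization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from colonynet.events import (
    CLASS_ORDER,
    WORKER_CLASSES,
    ClassRoster,
    FunctionalClass,
    TrophallaxisEvent,
    ValidationError,
)

#: Canonical order of the 6 possible between-class edges.
BETWEEN_CLASS_EDGES: tuple[tuple[FunctionalClass, FunctionalClass], ...] = tuple(
    itertools.combinations(CLASS_ORDER, 2)
)


@dataclass
class FunctionNetwork:
    """4-node class-to-class network with duration weights (seconds)."""

    colony: str
    night: int
    #: weight per unordered class pair, keyed by (class_a, class_b) in
    #: CLASS_ORDER; includes worker self-pairs, never (queen, queen).
    weights: dict[tuple[FunctionalClass, FunctionalClass], float] = field(
        default_factory=dict
    )

    def weight(self, a: FunctionalClass, b: FunctionalClass) -> float:
        return self.weights.get(_class_pair(a, b), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class_a": a.short, "class_b": b.short, "weight_s": w}
            for (a, b), w in sorted(
                self.weights.items(),
                key=lambda kv: (CLASS_ORDER.index(kv[0][0]), CLASS_ORDER.index(kv[0][1])),
            )
        ]
        return pd.DataFrame(rows, columns=["class_a", "class_b", "weight_s"])


@dataclass(frozen=True)
class SubgraphPattern:
    """Canonical id of a functional-network connection pattern.

    ``id`` lists the present between-class edges in fixed class order,
    prefixed by the edge count (e.g. ``"2:AF-IF|IF-NW"``); worker
    self-loop presence is carried in ``loops`` and excluded from the id.
    """

    id: str
    edge_count: int
    loops: tuple[str, ...] = ()


@dataclass
class NullEnsemble:
    """Pattern census over degree-preserving randomized realizations."""

    colony: str
    night: int
    n_reps: int
    n_swaps: int
    pattern_counts: dict[str, int]
    empirical_pattern: str
    seed: int | None = None

    @property
    def total(self) -> int:
        return sum(self.pattern_counts.values())


def _class_pair(
    a: FunctionalClass, b: FunctionalClass
) -> tuple[FunctionalClass, FunctionalClass]:
    if CLASS_ORDER.index(a) <= CLASS_ORDER.index(b):
        return (a, b)
    return (b, a)


def collapse(
    events: Sequence[TrophallaxisEvent], roster: ClassRoster
) -> FunctionNetwork:
    """Sum event durations by class pair for one colony-night.

    All four classes appear as nodes even with no members or no
    interactions; worker self-pairs accumulate within-class durations.
    """
    nights = {(e.colony, e.night) for e in events}
    if len(nights) > 1:
        raise ValidationError(f"events span multiple colony-nights: {sorted(nights)}")
    if events:
        colony, night = next(iter(nights))
    else:
        raise ValidationError("cannot infer colony-night from an empty event list; "
                              "use collapse_window instead")
    return collapse_window(events, roster, colony, night)


def collapse_window(
    events: Sequence[TrophallaxisEvent],
    roster: ClassRoster,
    colony: str,
    night: int,
) -> FunctionNetwork:
    weights: dict[tuple[FunctionalClass, FunctionalClass], float] = {}
    for a, b in BETWEEN_CLASS_EDGES:
        weights[(a, b)] = 0.0
    for c in WORKER_CLASSES:
        weights[(c, c)] = 0.0
    classes = roster.classes_for(colony, night)
    for e in events:
        if e.colony != colony or e.night != night:
            raise ValidationError("event outside the collapsed colony-night")
        try:
            ca, cb = classes[e.ant_a], classes[e.ant_b]
        except KeyError as err:
            raise ValidationError(f"event participant {err} missing from roster")
        weights[_class_pair(ca, cb)] += e.duration_s
    return FunctionNetwork(colony=colony, night=night, weights=weights)


def classify_pattern(
    fnet: FunctionNetwork, *, min_weight_s: float = 0.0
) -> SubgraphPattern:
    """Canonical connection pattern of a functional network.

    An edge is present when its weight strictly exceeds
    ``min_weight_s`` (default: any positive duration).
    """
    present = [
        f"{a.short}-{b.short}"
        for a, b in BETWEEN_CLASS_EDGES
        if fnet.weight(a, b) > min_weight_s
    ]
    loops = tuple(
        c.short for c in WORKER_CLASSES if fnet.weight(c, c) > min_weight_s
    )
    return SubgraphPattern(
        id=f"{len(present)}:{'|'.join(present)}",
        edge_count=len(present),
        loops=loops,
    )


def enumerate_patterns(include_self_loops: bool = False) -> list[SubgraphPattern]:
    """All nonempty connection patterns on the 4 labeled class nodes.

    Without self-loops: every nonempty subset of the 6 between-class
    edges.  With self-loops: every combination of between-class edges
    and worker self-loops with at least one edge or loop.  The count is
    derived by enumeration, never assumed.
    """
    patterns: list[SubgraphPattern] = []
    edge_subsets = []
    for r in range(len(BETWEEN_CLASS_EDGES) + 1):
        edge_subsets.extend(itertools.combinations(BETWEEN_CLASS_EDGES, r))
    loop_subsets: list[tuple] = [()]
    if include_self_loops:
        loop_subsets = []
        for r in range(len(WORKER_CLASSES) + 1):
            loop_subsets.extend(itertools.combinations(WORKER_CLASSES, r))
    for edges in edge_subsets:
        for loops in loop_subsets:
            if not edges and not loops:
                continue
            pid = f"{len(edges)}:{'|'.join(f'{a.short}-{b.short}' for a, b in edges)}"
            patterns.append(
                SubgraphPattern(
                    id=pid,
                    edge_count=len(edges),
                    loops=tuple(c.short for c in loops),
                )
            )
    return patterns


def double_edge_swap(
    net: nx.Graph,
    n_swaps: int,
    rng: np.random.Generator,
    *,
    count_proposals: bool = False,
    max_proposals: int | None = None,
) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Repeatedly picks two edges (u,v),(x,y) and rewires them to
    (u,y),(x,v); proposals that would create a self-loop or a parallel
    edge are rejected and resampled.  By default ``n_swaps`` counts
    *successful* swaps (``count_proposals=True`` counts proposals
    instead, accepted or not).  Node attributes (class labels) are
    untouched.  If no valid swap is found within ``max_proposals``
    (default ``100 * n_swaps``), the graph accumulated so far is
    returned with a warning attribute ``swap_exhausted=True``.
    """
    G = net.copy()
    edges = list(G.edges())
    if len(edges) < 2 or n_swaps <= 0:
        return G
    if max_proposals is None:
        max_proposals = max(100 * n_swaps, 1000)
    done = 0
    proposals = 0
    while done < n_swaps and proposals < max_proposals:
        proposals += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            if count_proposals:
                done += 1
            continue
        u, v = edges[i]
        x, y = edges[j]
        # randomize orientation of the second edge
        if rng.integers(0, 2):
            x, y = y, x
        ok = (
            u != y
            and x != v
            and not G.has_edge(u, y)
            and not G.has_edge(x, v)
        )
        if ok:
            du = G[u][v]
            dx = G[x][y]
            G.remove_edge(u, v)
            G.remove_edge(x, y)
            G.add_edge(u, y, **du)
            G.add_edge(x, v, **dx)
            edges[i] = (u, y)
            edges[j] = (x, v)
            if not count_proposals:
                done += 1
        if count_proposals:
            done += 1
    if done < n_swaps:
        G.graph["swap_exhausted"] = True
    return G


def null_ensemble(
    net: nx.Graph,
    roster: ClassRoster,
    fnet: FunctionNetwork | None = None,
    n_reps: int = 100,
    n_swaps: int = 500,
    rng: np.random.Generator | int | None = None,
) -> NullEnsemble:
    """Pattern census of ``n_reps`` swap-randomized network realizations.

    Each repetition randomizes the individual-level network with
    ``n_swaps`` double-edge swaps, collapses it onto the fixed class
    roster (edge presence only — every randomized contact contributes
    one unit weight), and classifies the resulting pattern.

    ``fnet`` optionally supplies the empirical functional network whose
    pattern is recorded alongside the null counts.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    colony = net.graph.get("colony")
    night = net.graph.get("night")
    classes = roster.classes_for(colony, night)
    counts: dict[str, int] = {}
    for _ in range(n_reps):
        randomized = double_edge_swap(net, n_swaps, rng)
        pattern = _pattern_from_graph(randomized, classes)
        counts[pattern.id] = counts.get(pattern.id, 0) + 1
    empirical = (
        classify_pattern(fnet).id
        if fnet is not None
        else _pattern_from_graph(net, classes).id
    )
    return NullEnsemble(
        colony=colony,
        night=night,
        n_reps=n_reps,
        n_swaps=n_swaps,
        pattern_counts=counts,
        empirical_pattern=empirical,
    )


def _pattern_from_graph(
    G: nx.Graph, classes: dict[str, FunctionalClass]
) -> SubgraphPattern:
    present: set[tuple[FunctionalClass, FunctionalClass]] = set()
    loops: set[FunctionalClass] = set()
    for u, v in G.edges():
        cu, cv = classes[u], classes[v]
        if cu == cv:
            loops.add(cu)
        else:
            present.add(_class_pair(cu, cv))
    ordered = [e for e in BETWEEN_CLASS_EDGES if e in present]
    return SubgraphPattern(
        id=f"{len(ordered)}:{'|'.join(f'{a.short}-{b.short}' for a, b in ordered)}",
        edge_count=len(ordered),
        loops=tuple(c.short for c in sorted(loops, key=CLASS_ORDER.index)),
    )


def ensemble_histogram(ensembles: Sequence[NullEnsemble]) -> pd.DataFrame:
    """Aggregate expected-vs-realized pattern counts across colony-nights."""
    expected: dict[str, int] = {}
    observed: dict[str, int] = {}
    for ens in ensembles:
        for pid, c in ens.pattern_counts.items():
            expected[pid] = expected.get(pid, 0) + c
        observed[ens.empirical_pattern] = observed.get(ens.empirical_pattern, 0) + 1
    ids = sorted(set(expected) | set(observed))
    return pd.DataFrame(
        {
            "pattern_id": ids,
            "expected_count": [expected.get(i, 0) for i in ids],
            "observed_count": [observed.get(i, 0) for i in ids],
        }
    )
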