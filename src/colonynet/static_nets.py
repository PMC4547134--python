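"""Per colony-night static trophallaxis networks and node metrics.

Networks are simple undirected graphs: one node per rostered ant
(isolates included), one edge per interacting dyad with the number of
discrete events stored as the ``count`` edge attribute.  Degree,
betweenness and closeness treat the graph as unweighted; Burt's
constraint uses event counts as tie strengths.

Conventions for disconnected graphs: closeness is the reciprocal of the
mean geodesic distance to *reachable* nodes only, and is undefined
(``NaN``) for isolates rather than zero, so isolated ants do not inject
a spurious group difference downstream.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from colonynet.events import (
    ClassRoster,
    ObservationWindow,
    TrophallaxisEvent,
    ValidationError,
)


def build_static_network(
    events: Sequence[TrophallaxisEvent],
    roster: ClassRoster | None,
    window: ObservationWindow,
) -> nx.Graph:
    """Build the simple interaction graph for one colony-night.

    Every ant rostered that night appears as a node (isolates
    included); each interacting dyad becomes a single edge whose
    ``count`` attribute is the number of discrete events.
    """
    G = nx.Graph(colony=window.colony, night=window.night)
    if roster is not None:
        for ant, cls in roster.classes_for(window.colony, window.night).items():
            G.add_node(ant, functional_class=cls.value)
    for e in events:
        if e.colony != window.colony or e.night != window.night:
            raise ValidationError(
                f"event from {e.colony}/{e.night} mixed into network "
                f"{window.colony}/{window.night}"
            )
        if G.has_edge(e.ant_a, e.ant_b):
            G[e.ant_a][e.ant_b]["count"] += 1
        else:
            G.add_edge(e.ant_a, e.ant_b, count=1)
    return G


def degree(net: nx.Graph) -> dict[str, int]:
    """Number of distinct interaction partners (unweighted degree)."""
    return dict(net.degree())


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness.

    Equal-length shortest paths share credit fractionally; endpoints
    are excluded.
    """
    return nx.betweenness_centrality(net, normalized=False)


def closeness(net: nx.Graph) -> dict[str, float]:
    """Reciprocal of mean geodesic distance over reachable nodes.

    Computed within connected components; isolates get ``NaN``
    (undefined), not zero.
    """
    raw = nx.closeness_centrality(net, wf_improved=False)
    return {
        v: (raw[v] if net.degree(v) > 0 else math.nan) for v in net.nodes
    }


def burts_constraint(
    net: nx.Graph, *, weighted: bool = True
) -> dict[str, float]:
    """Burt's constraint: redundancy of a node's contacts.

    ``c_i = sum_j (p_ij + sum_q p_iq p_qj)^2`` with ``p_ij`` the share
    of i's total tie strength invested in j.  Event counts are the tie
    strengths by default (``weighted=False`` uses binary ties).
    Isolates are undefined (``NaN``).
    """
    weight = "count" if weighted else None
    out: dict[str, float] = {}
    for v in net.nodes:
        if net.degree(v) == 0:
            out[v] = math.nan
        else:
            out[v] = float(_node_constraint(net, v, weight))
    return out


def _node_constraint(net: nx.Graph, v, weight: str | None) -> float:
    # direct evaluation of Burt's formula; p_ij normalized over i's ties
    nbrs = list(net[v])
    strengths = {
        j: (net[v][j].get(weight, 1.0) if weight else 1.0) for j in nbrs
    }
    total = sum(strengths.values())
    p = {j: strengths[j] / total for j in nbrs}
    c = 0.0
    for j in nbrs:
        indirect = 0.0
        for q in nbrs:
            if q == j:
                continue
            q_nbrs = net[q]
            if j in q_nbrs:
                qs = {
                    k: (q_nbrs[k].get(weight, 1.0) if weight else 1.0)
                    for k in q_nbrs
                }
                qt = sum(qs.values())
                indirect += p[q] * (qs[j] / qt)
        c += (p[j] + indirect) ** 2
    return c


def node_metrics_table(
    net: nx.Graph, roster: ClassRoster | None = None
) -> pd.DataFrame:
    """All four node metrics for one network as a tidy table.

    Columns: colony, night, ant, functional_class, degree, betweenness,
    closeness, constraint.  Undefined metrics are ``NaN``.
    """
    colony = net.graph.get("colony")
    night = net.graph.get("night")
    deg = degree(net)
    btw = betweenness(net)
    clo = closeness(net)
    con = burts_constraint(net)
    rows = []
    for ant in sorted(net.nodes):
        cls = net.nodes[ant].get("functional_class")
        if cls is None and roster is not None and colony is not None:
            cls = roster.get(colony, night, ant).value
        rows.append(
            {
                "colony": colony,
                "night": night,
                "ant": ant,
                "functional_class": cls,
                "degree": deg[ant],
                "betweenness": btw[ant],
                "closeness": clo[ant],
                "constraint": con[ant],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "colony",
            "night",
            "ant",
            "functional_class",
            "degree",
            "betweenness",
            "closeness",
            "constraint",
        ],
    )


def export_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or a 3-column weighted edge list."""
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v, data in net.edges(data=True):
                fh.write(f"{u} {v} {data.get('count', 1)}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    """Read a network previously written by :func:`export_network`."""
    if fmt == "graphml":
        G = nx.read_graphml(path)
        for _, _, data in G.edges(data=True):
            if "count" in data:
                data["count"] = int(data["count"])
        return G
    if fmt == "edgelist":
        G = nx.Graph()
        with open(path) as fh:
            for line in fh:
                u, v, c = line.split()
                G.add_edge(u, v, count=int(c))
        return G
    raise ValueError(f"unknown export format {fmt!r}")
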