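"""Brute-force oracles, independent of the library implementations.

All-shortest-paths centralities by explicit path enumeration over a
plain adjacency-dict graph, and a direct trajectory likelihood for the
continuous-time walk (exponential holding times, multinomial jumps).
"""

from __future__ import annotations

import math
from collections import deque
from itertools import permutations

import numpy as np


def adjacency(edges, nodes=None) -> dict:
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for n in nodes or []:
        adj.setdefault(n, set())
    return adj


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Every geodesic from s to t, by depth-first expansion over BFS levels."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_betweenness(adj: dict) -> dict:
    """Unnormalized betweenness by enumerating every shortest path."""
    nodes = sorted(adj)
    btw = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    btw[v] += 1.0 / len(paths)
    return btw


def brute_closeness(adj: dict) -> dict:
    """1 / mean geodesic distance over reachable nodes; NaN for isolates."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        others = [d for u, d in dist.items() if u != v]
        out[v] = len(others) / sum(others) if others else math.nan
    return out


def trajectory_loglik(beta, visits, duration, grid, group, spec) -> float:
    """Direct exponential-holding / multinomial-jump log-likelihood.

    ``visits`` is the (cell, t_enter) list of one track.  Each completed
    holding of length tau in cell i contributes
    ``log(Lambda_i) - Lambda_i tau + log(lambda_ij / Lambda_i)`` for the
    jump to j; the final censored holding contributes the survival term
    ``-Lambda_i tau`` only.
    """
    beta = np.asarray(beta, dtype=float)
    ll = 0.0
    for k, (cell, t0) in enumerate(visits):
        t1 = visits[k + 1][1] if k + 1 < len(visits) else duration
        tau = t1 - t0
        nbrs = grid.neighbors(cell)
        lams = np.array(
            [math.exp(float(spec.design_row(group, cell, j, grid) @ beta)) for j in nbrs]
        )
        total = lams.sum()
        ll += -total * tau
        if k + 1 < len(visits):
            j = visits[k + 1][0]
            ll += math.log(lams[nbrs.index(j)])
    return ll


def temporal_reach_bruteforce(contacts, source, t_from=0.0) -> set:
    """Reachable set by exhaustive enumeration of time-respecting chains."""
    reached = {source: t_from}
    # iterate to fixpoint over all contacts (handles equal-time relays)
    changed = True
    while changed:
        changed = False
        for a, b, t in contacts:
            for x, y in ((a, b), (b, a)):
                if x in reached and reached[x] <= t and reached.get(y, math.inf) > t:
                    reached[y] = t
                    changed = True
    return set(reached)
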