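"""Nest-grid movement: residence maps and a CTDS random-walk model.

Ant locations are recorded as time-stamped visits to 1 cm grid cells of
a four-chambered nest.  Movement is modelled as a continuous-time
discrete-space (CTDS) Markov chain: from cell i the ant jumps to an
adjacent cell j with rate

    lambda_ij = exp(beta . z_ij)

where the covariates z_ij encode group-specific motility (intercepts
per movement group), modulation of speed when the ant shares a chamber
with the queen, and a directional "toward queen" indicator measuring
attraction/avoidance.  The likelihood is the standard counting-process
(Poisson) form: each visit of holding time tau contributes, for every
neighbour j, a term ``y log lambda_ij - tau lambda_ij`` with y = 1 for
the neighbour actually moved to.  Final visits censored by the window
end contribute exposure with no event.

The model API follows the fit/results pattern of statsmodels:
``CTDSModel(records).fit()`` returns a :class:`CTDSResults` with
estimates, standard errors from the observed information, and a
``summary()`` table.
"""

from __future__ import annotations

import json
import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from colonynet.events import (
    ClassRoster,
    FunctionalClass,
    ValidationError,
)
from colonynet.stats import TestResult, two_sided_t_test

logger = logging.getLogger(__name__)

Cell = tuple[int, int]

SECONDS_PER_ANT_DAY = 86_400.0

#: movement analysis pools active and inactive foragers into one group
MOVEMENT_GROUPS = ("forager", "nest_worker", "queen")

_CLASS_TO_GROUP = {
    FunctionalClass.ACTIVE_FORAGER: "forager",
    FunctionalClass.INACTIVE_FORAGER: "forager",
    FunctionalClass.NEST_WORKER: "nest_worker",
    FunctionalClass.QUEEN: "queen",
}


def movement_group(cls: FunctionalClass) -> str:
    return _CLASS_TO_GROUP[cls]


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass
class GridSpec:
    """Discrete nest grid: cells with chamber ids plus passage edges.

    Adjacency is 4-neighbour within a chamber; chambers communicate
    only through designated passage edges.
    """

    chambers: dict[Cell, int]
    passages: list[tuple[Cell, Cell]] = field(default_factory=list)
    queen_cell: Cell | None = None

    def __post_init__(self) -> None:
        self._adj: dict[Cell, list[Cell]] = {c: [] for c in self.chambers}
        for (r, c), ch in self.chambers.items():
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (r + dr, c + dc)
                if self.chambers.get(nb) == ch:
                    self._adj[(r, c)].append(nb)
        for a, b in self.passages:
            if a not in self.chambers or b not in self.chambers:
                raise ValidationError(f"passage {a}-{b} references unknown cell")
            if b not in self._adj[a]:
                self._adj[a].append(b)
                self._adj[b].append(a)
        for nbrs in self._adj.values():
            nbrs.sort()
        self._queen_dist: dict[Cell, float] | None = None

    @property
    def cells(self) -> list[Cell]:
        return sorted(self.chambers)

    @property
    def n_cells(self) -> int:
        return len(self.chambers)

    def neighbors(self, cell: Cell) -> list[Cell]:
        return self._adj[cell]

    def chamber(self, cell: Cell) -> int:
        return self.chambers[cell]

    def same_chamber(self, a: Cell, b: Cell) -> bool:
        return self.chambers[a] == self.chambers[b]

    def distance_to_queen(self, cell: Cell) -> float:
        """Grid (geodesic) distance to the queen's cell; inf if cut off."""
        if self.queen_cell is None:
            raise ValidationError("grid has no queen cell")
        if self._queen_dist is None:
            self._queen_dist = self._bfs(self.queen_cell)
        return self._queen_dist.get(cell, math.inf)

    def _bfs(self, source: Cell) -> dict[Cell, float]:
        dist = {source: 0.0}
        q = deque([source])
        while q:
            u = q.popleft()
            for v in self._adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        return dist

    # -- constructors -------------------------------------------------

    @classmethod
    def paper_like(cls) -> "GridSpec":
        """Four chambers, 63 cells total (16+16+16+15), 1 cm resolution.

        Chambers sit in a row (4x4 blocks, the innermost lacking one
        corner cell); consecutive chambers share a single passage edge.
        The queen sits in the innermost chamber.
        """
        chambers: dict[Cell, int] = {}
        for ch in range(4):
            for r in range(4):
                for c in range(4):
                    chambers[(r, 4 * ch + c)] = ch
        del chambers[(3, 15)]  # innermost chamber has 15 cells
        passages = [((1, 4 * ch + 3), (1, 4 * ch + 4)) for ch in range(3)]
        return cls(chambers=chambers, passages=passages, queen_cell=(1, 14))

    @classmethod
    def single_chamber(cls, rows: int, cols: int, queen_cell: Cell | None = None) -> "GridSpec":
        chambers = {(r, c): 0 for r in range(rows) for c in range(cols)}
        return cls(chambers=chambers, passages=[], queen_cell=queen_cell)

    # -- serialization ------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "cells": [[r, c, ch] for (r, c), ch in sorted(self.chambers.items())],
            "passages": [[list(a), list(b)] for a, b in self.passages],
            "queen_cell": list(self.queen_cell) if self.queen_cell else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GridSpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            chambers={(r, c): ch for r, c, ch in payload["cells"]},
            passages=[(tuple(a), tuple(b)) for a, b in payload["passages"]],
            queen_cell=tuple(payload["queen_cell"]) if payload["queen_cell"] else None,
        )


# ---------------------------------------------------------------------------
# Tracks and residence
# ---------------------------------------------------------------------------


@dataclass
class MovementTrack:
    """Ordered cell visits of one ant on one night.

    Each visit ``(cell, t_enter_s)`` lasts until the next visit's entry
    or the window end.
    """

    colony: str
    night: int
    ant: str
    visits: list[tuple[Cell, float]]
    window_s: float = 1200.0

    def __post_init__(self) -> None:
        times = [t for _, t in self.visits]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError(
                f"{self.ant}: visit times must be strictly increasing"
            )
        if times and (times[0] < 0 or times[-1] > self.window_s):
            raise ValidationError(f"{self.ant}: visit outside the window")

    def residences(self) -> list[tuple[Cell, float, float]]:
        """(cell, t_enter, holding seconds) per visit, censored at window end."""
        out = []
        for k, (cell, t0) in enumerate(self.visits):
            t1 = self.visits[k + 1][1] if k + 1 < len(self.visits) else self.window_s
            out.append((cell, t0, t1 - t0))
        return out

    @property
    def n_moves(self) -> int:
        return max(0, len(self.visits) - 1)

    @property
    def tracked_seconds(self) -> float:
        if not self.visits:
            return 0.0
        return self.window_s - self.visits[0][1]


def write_tracks(tracks: Iterable[MovementTrack], path) -> None:
    rows = []
    for tr in tracks:
        for (r, c), t in tr.visits:
            rows.append(
                {
                    "colony": tr.colony,
                    "night": tr.night,
                    "ant": tr.ant,
                    "time_s": t,
                    "cell_row": r,
                    "cell_col": c,
                }
            )
    pd.DataFrame(
        rows, columns=["colony", "night", "ant", "time_s", "cell_row", "cell_col"]
    ).to_csv(path, index=False, float_format="%.17g")


def read_tracks(path, window_s: float = 1200.0) -> list[MovementTrack]:
    df = pd.read_csv(path, float_precision="round_trip")
    tracks = []
    for (colony, night, ant), g in df.groupby(["colony", "night", "ant"], sort=True):
        g = g.sort_values("time_s")
        visits = [
            ((int(r.cell_row), int(r.cell_col)), float(r.time_s))
            for r in g.itertuples(index=False)
        ]
        tracks.append(
            MovementTrack(
                colony=str(colony), night=int(night), ant=str(ant),
                visits=visits, window_s=window_s,
            )
        )
    return tracks


def residence_map(
    tracks: Sequence[MovementTrack],
    grid: GridSpec,
    roster: ClassRoster | None = None,
    *,
    ant_days: bool = False,
) -> dict[str, dict[Cell, float]]:
    """Per-cell summed residence time, aggregated by movement group.

    Returns ``{group: {cell: ant_seconds}}`` (or ant-days with
    ``ant_days=True``); without a roster everything lands in group
    ``"all"``.  Total residence equals total tracked seconds exactly.
    """
    out: dict[str, dict[Cell, float]] = {}
    for tr in tracks:
        if roster is not None:
            group = movement_group(roster.get(tr.colony, tr.night, tr.ant))
        else:
            group = "all"
        acc = out.setdefault(group, {})
        for cell, _, hold in tr.residences():
            if cell not in grid.chambers:
                raise ValidationError(f"track visits cell {cell} outside the grid")
            acc[cell] = acc.get(cell, 0.0) + hold
    if ant_days:
        out = {
            g: {c: s / SECONDS_PER_ANT_DAY for c, s in acc.items()}
            for g, acc in out.items()
        }
    return out


def spatial_spread_index(
    rmap: Mapping[str, Mapping[Cell, float]],
    grid: GridSpec,
    threshold_s: float = 0.0,
) -> dict[str, float]:
    """Fraction of nest cells with residence above ``threshold_s``, per group."""
    return {
        group: sum(1 for s in acc.values() if s > threshold_s) / grid.n_cells
        for group, acc in rmap.items()
    }


def residence_table(rmap: Mapping[str, Mapping[Cell, float]]) -> pd.DataFrame:
    rows = [
        {"group": g, "cell_row": r, "cell_col": c, "ant_seconds": s}
        for g, acc in sorted(rmap.items())
        for (r, c), s in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["group", "cell_row", "cell_col", "ant_seconds"])


# ---------------------------------------------------------------------------
# CTDS model specification and records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CTDSSpec:
    """Covariate specification for the CTDS transition rates.

    The default ("social") specification uses group-specific intercepts
    (log base motility per movement group), a queen-same-chamber
    indicator interacted with the worker groups (speed modulation near
    the queen), a toward-queen directional indicator (j strictly closer
    to the queen's cell than i) and its forager interaction
    (directional avoidance/attraction).  Disabling every optional block
    leaves a single intercept, whose MLE has the closed form
    (number of moves) / (summed record exposure).
    """

    per_group_intercepts: bool = True
    queen_chamber_by_group: bool = True
    toward_queen: bool = True
    toward_queen_by_group: bool = True

    @classmethod
    def intercept_only(cls) -> "CTDSSpec":
        return cls(
            per_group_intercepts=False,
            queen_chamber_by_group=False,
            toward_queen=False,
            toward_queen_by_group=False,
        )

    @property
    def param_names(self) -> list[str]:
        names = (
            [f"log_rate_{g}" for g in MOVEMENT_GROUPS]
            if self.per_group_intercepts
            else ["log_rate"]
        )
        if self.queen_chamber_by_group:
            names += ["queen_chamber_x_forager", "queen_chamber_x_nest_worker"]
        if self.toward_queen:
            names += ["toward_queen"]
        if self.toward_queen_by_group:
            names += ["toward_queen_x_forager"]
        return names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def design_row(
        self, group: str, cell_i: Cell, cell_j: Cell, grid: GridSpec
    ) -> np.ndarray:
        z = []
        if self.per_group_intercepts:
            z += [1.0 if group == g else 0.0 for g in MOVEMENT_GROUPS]
        else:
            z += [1.0]
        needs_queen = (
            self.queen_chamber_by_group or self.toward_queen or self.toward_queen_by_group
        )
        if needs_queen and grid.queen_cell is None:
            raise ValidationError("covariates need a queen cell on the grid")
        if self.queen_chamber_by_group:
            qc = 1.0 if grid.same_chamber(cell_i, grid.queen_cell) else 0.0
            z += [qc * (group == "forager"), qc * (group == "nest_worker")]
        if self.toward_queen or self.toward_queen_by_group:
            tq = (
                1.0
                if grid.distance_to_queen(cell_j) < grid.distance_to_queen(cell_i)
                else 0.0
            )
            if self.toward_queen:
                z += [tq]
            if self.toward_queen_by_group:
                z += [tq * (group == "forager")]
        return np.asarray(z, dtype=float)


@dataclass
class CTDSRecords:
    """Expanded counting-process records for the CTDS likelihood.

    One row per (visit, adjacent cell): design row ``Z``, exposure
    (holding time), and outcome 1 for the neighbour actually moved to.
    """

    Z: np.ndarray
    exposure: np.ndarray
    y: np.ndarray
    param_names: list[str]
    meta: pd.DataFrame  # ant, group, visit index per record

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_moves(self) -> int:
        return int(self.y.sum())


def build_ctds_records(
    tracks: Sequence[MovementTrack],
    grid: GridSpec,
    roster: ClassRoster | None = None,
    spec: CTDSSpec | None = None,
) -> CTDSRecords:
    """Expand visit histories into per-neighbour transition records.

    Every visit with holding time tau yields one record per adjacent
    cell, with outcome 1 for the observed destination; censored final
    visits contribute exposure-only records.  Observed jumps to
    non-adjacent cells (tracking gaps) are excluded with a warning.
    """
    if spec is None:
        spec = CTDSSpec()
    Zs, taus, ys, meta = [], [], [], []
    n_skipped = 0
    for tr in tracks:
        if roster is not None:
            group = movement_group(roster.get(tr.colony, tr.night, tr.ant))
        else:
            group = "nest_worker"
        res = tr.residences()
        for k, (cell, _, hold) in enumerate(res):
            nxt = res[k + 1][0] if k + 1 < len(res) else None
            if nxt is not None and nxt not in grid.neighbors(cell):
                n_skipped += 1
                continue
            if hold <= 0:
                continue
            for nb in grid.neighbors(cell):
                Zs.append(spec.design_row(group, cell, nb, grid))
                taus.append(hold)
                ys.append(1.0 if nb == nxt else 0.0)
                meta.append((tr.ant, group, k))
    if n_skipped:
        logger.warning("excluded %d non-adjacent jumps (tracking gaps)", n_skipped)
    if not Zs:
        raise ValidationError("no usable transition records")
    return CTDSRecords(
        Z=np.vstack(Zs),
        exposure=np.asarray(taus),
        y=np.asarray(ys),
        param_names=spec.param_names,
        meta=pd.DataFrame(meta, columns=["ant", "group", "visit"]),
    )


def ctds_loglik(beta: np.ndarray, records: CTDSRecords) -> float:
    """Poisson-process log-likelihood ``sum y (b.z) - tau exp(b.z)``.

    Equal, up to an additive beta-free constant, to the exponential
    holding / multinomial jump likelihood of the observed trajectories.
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(records.Z)):
        raise ValidationError("non-finite covariates")
    eta = records.Z @ beta
    return float(records.y @ eta - records.exposure @ np.exp(eta))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class CTDSModel:
    """CTDS random-walk model over expanded transition records.

    Build from records (or via :meth:`from_tracks`) and call
    :meth:`fit`; the log-likelihood is globally concave in beta, so the
    Newton iteration converges from any start.
    """

    def __init__(self, records: CTDSRecords):
        self.records = records
        self.param_names = records.param_names

    @classmethod
    def from_tracks(
        cls,
        tracks: Sequence[MovementTrack],
        grid: GridSpec,
        roster: ClassRoster | None = None,
        spec: CTDSSpec | None = None,
    ) -> "CTDSModel":
        return cls(build_ctds_records(tracks, grid, roster, spec))

    def loglike(self, beta: np.ndarray) -> float:
        return ctds_loglik(beta, self.records)

    def score(self, beta: np.ndarray) -> np.ndarray:
        mu = self.records.exposure * np.exp(self.records.Z @ beta)
        return self.records.Z.T @ (self.records.y - mu)

    def information(self, beta: np.ndarray) -> np.ndarray:
        """Observed information (equals expected for this log link)."""
        mu = self.records.exposure * np.exp(self.records.Z @ beta)
        return (self.records.Z * mu[:, None]).T @ self.records.Z

    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 100,
        tol: float = 1e-10,
        cap: float = 30.0,
    ) -> "CTDSResults":
        """Maximize the likelihood by Newton-Raphson with step halving.

        Separation (a covariate pattern with exposure but no possible
        events, or vice versa) drives an estimate toward +/-inf; such
        coefficients are capped at ``+/-cap`` and flagged.
        """
        rec = self.records
        if rec.n_moves == 0:
            raise ValidationError("no observed moves; rates are not identifiable")
        p = rec.Z.shape[1]
        beta = np.zeros(p) if start is None else np.asarray(start, dtype=float)
        # neutral start: common log rate
        if start is None:
            beta[:] = 0.0
            base = math.log(rec.n_moves / float(rec.exposure.sum()))
            beta[: (3 if p >= 3 else 1)] = base if p >= 1 else 0.0
        ll = self.loglike(beta)
        converged = False
        for _ in range(maxiter):
            g = self.score(beta)
            I = self.information(beta)
            try:
                step = np.linalg.solve(I, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(I, g, rcond=None)[0]
            t = 1.0
            while t > 1e-8:
                cand = np.clip(beta + t * step, -cap, cap)
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                t /= 2.0
            if np.max(np.abs(cand - beta)) < tol:
                beta, ll = cand, ll_new
                converged = True
                break
            beta, ll = cand, ll_new
        capped = np.abs(beta) >= cap - 1e-9
        if capped.any():
            logger.warning(
                "separation suspected: capped coefficient(s) %s",
                [self.param_names[i] for i in np.flatnonzero(capped)],
            )
        I = self.information(beta)
        try:
            cov = np.linalg.inv(I)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            bse = np.full(p, np.nan)
        return CTDSResults(
            model=self,
            params=beta,
            bse=bse,
            cov_params=cov,
            llf=ll,
            converged=converged,
            separation=bool(capped.any()),
        )


@dataclass
class CTDSResults:
    """Fitted CTDS model: estimates, uncertainties, diagnostics."""

    model: CTDSModel
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    separation: bool

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = sps.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def to_frame(self) -> pd.DataFrame:
        z = np.divide(
            self.params, self.bse, out=np.full_like(self.params, np.nan),
            where=self.bse > 0,
        )
        return pd.DataFrame(
            {
                "param": self.param_names,
                "estimate": self.params,
                "se": self.bse,
                "z": z,
                "p": 2 * sps.norm.sf(np.abs(z)),
            }
        )

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "CTDS random-walk model",
            f"  records: {self.model.records.n_records}   "
            f"moves: {self.model.records.n_moves}   "
            f"log-likelihood: {self.llf:.3f}",
            f"  converged: {self.converged}   separation: {self.separation}",
            "",
            f"  {'param':<28}{'estimate':>10}{'se':>9}{'z':>8}{'p':>9}",
        ]
        for r in df.itertuples(index=False):
            lines.append(
                f"  {r.param:<28}{r.estimate:>10.4f}{r.se:>9.4f}"
                f"{r.z:>8.2f}{r.p:>9.4f}"
            )
        return "\n".join(lines)


def fit_ctds(
    records: CTDSRecords, start: np.ndarray | None = None
) -> CTDSResults:
    """Convenience wrapper: fit the CTDS model on prepared records."""
    return CTDSModel(records).fit(start=start)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_ctds(
    beta: np.ndarray,
    grid: GridSpec,
    duration_s: float,
    start_cell: Cell,
    rng: np.random.Generator,
    *,
    group: str = "nest_worker",
    spec: CTDSSpec | None = None,
    colony: str = "sim",
    night: int = 1,
    ant: str = "sim",
    t_start: float = 0.0,
) -> MovementTrack:
    """Gillespie simulation of the CTDS walk, truncated at the window end.

    Holding time in cell i is Exponential(sum_j lambda_ij); the jump
    goes to neighbour j with probability lambda_ij / sum.  Zero total
    rate leaves the ant in place for the remaining window.
    """
    if spec is None:
        spec = CTDSSpec()
    beta = np.asarray(beta, dtype=float)
    t = t_start
    cell = start_cell
    visits = [(cell, t)]
    while True:
        nbrs = grid.neighbors(cell)
        if not nbrs:
            break
        rates = np.array(
            [math.exp(float(spec.design_row(group, cell, j, grid) @ beta)) for j in nbrs]
        )
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration_s:
            break
        cell = nbrs[rng.choice(len(nbrs), p=rates / total)]
        visits.append((cell, t))
    return MovementTrack(
        colony=colony, night=night, ant=ant, visits=visits, window_s=duration_s
    )


# ---------------------------------------------------------------------------
# Movement contrasts
# ---------------------------------------------------------------------------


def movement_contrasts(
    tracks: Sequence[MovementTrack],
    roster: ClassRoster,
    grid: GridSpec,
    queen_cell: Cell | None = None,
) -> pd.DataFrame:
    """The two group contrasts of per-ant movement rates.

    (a) overall mobility: moves per tracked second, forager vs nest
    worker; (b) queen-chamber speed modulation: each ant's rate while
    sharing the queen's chamber minus its rate elsewhere, contrasted
    forager vs nest worker.  Nights are pooled within ant so the ant is
    the statistical unit; ants never observed in the queen's chamber
    (or only there) are excluded from (b) with a notice.
    """
    if queen_cell is None:
        queen_cell = grid.queen_cell
    if queen_cell is None:
        raise ValidationError("queen cell required for movement contrasts")

    per_ant: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    for tr in tracks:
        group = movement_group(roster.get(tr.colony, tr.night, tr.ant))
        key = f"{tr.colony}/{tr.ant}"
        groups[key] = group
        acc = per_ant.setdefault(
            key, {"moves": 0, "time": 0.0, "moves_qc": 0, "time_qc": 0.0,
                  "moves_other": 0, "time_other": 0.0}
        )
        res = tr.residences()
        for k, (cell, _, hold) in enumerate(res):
            moved = 1 if k + 1 < len(res) else 0
            acc["moves"] += moved
            acc["time"] += hold
            if grid.same_chamber(cell, queen_cell):
                acc["moves_qc"] += moved
                acc["time_qc"] += hold
            else:
                acc["moves_other"] += moved
                acc["time_other"] += hold

    rates: dict[str, list[float]] = {"forager": [], "nest_worker": []}
    diffs: dict[str, list[float]] = {"forager": [], "nest_worker": []}
    n_excluded = 0
    for key, acc in per_ant.items():
        g = groups[key]
        if g not in rates:
            continue
        if acc["time"] > 0:
            rates[g].append(acc["moves"] / acc["time"])
        if acc["time_qc"] > 0 and acc["time_other"] > 0:
            diffs[g].append(
                acc["moves_qc"] / acc["time_qc"] - acc["moves_other"] / acc["time_other"]
            )
        else:
            n_excluded += 1

    rows = []
    for name, data in (("overall_mobility", rates), ("queen_chamber_modulation", diffs)):
        a, b = data["forager"], data["nest_worker"]
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {
                    "contrast": name, "n_forager": len(a), "n_nest_worker": len(b),
                    "mean_forager": np.mean(a) if a else math.nan,
                    "mean_nest_worker": np.mean(b) if b else math.nan,
                    "t": math.nan, "df": math.nan, "p": math.nan,
                    "note": "skipped: a group has < 2 ants",
                }
            )
            continue
        res: TestResult = two_sided_t_test(a, b)
        rows.append(
            {
                "contrast": name, "n_forager": len(a), "n_nest_worker": len(b),
                "mean_forager": float(np.mean(a)),
                "mean_nest_worker": float(np.mean(b)),
                "t": res.statistic, "df": res.df, "p": res.p,
                "note": (
                    f"{n_excluded} ant(s) without queen-chamber occupancy excluded"
                    if name == "queen_chamber_modulation" and n_excluded
                    else res.note
                ),
            }
        )
    return pd.DataFrame(rows)
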