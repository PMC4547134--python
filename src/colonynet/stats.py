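"""Nonparametric group comparisons for node metrics and movement rates.

Kruskal–Wallis one-way ANOVA on ranks (tie-corrected), Dunn's pairwise
post-hoc z-tests with Benjamini–Hochberg adjustment, and a two-sided
t-test (Welch by default) for movement contrasts.

Pair sign convention: Dunn z is first-listed minus second-listed mean
rank, with groups kept in the order supplied (use the fixed class order
active forager, inactive forager, nest worker, queen for reproducible
signs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError(f"group {self.label!r} is empty")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError(f"group {self.label!r} contains non-finite values")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    note: str = ""


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adj: float


def _as_groups(groups: Sequence) -> list[GroupSample]:
    out = []
    for g in groups:
        if isinstance(g, GroupSample):
            out.append(g)
        else:
            label, values = g
            out.append(GroupSample(str(label), tuple(float(v) for v in values)))
    return out


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Tie-corrected Kruskal–Wallis H test.

    ``groups`` is a sequence of :class:`GroupSample` or ``(label,
    values)`` pairs.  Returns H, its degrees of freedom (k-1) and the
    chi-squared p-value.  All-identical data yields H = 0, p = 1.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    n_total = sum(len(g.values) for g in gs)
    if n_total < 3:
        raise ValueError("Kruskal-Wallis requires at least 3 observations")
    pooled = np.concatenate([g.values for g in gs])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, df=len(gs) - 1, p=1.0)
    stat, p = sps.kruskal(*[g.values for g in gs])
    return TestResult(statistic=float(stat), df=len(gs) - 1, p=float(p))


def dunn_test(groups: Sequence) -> list[PairwiseResult]:
    """Dunn's post-hoc pairwise z-tests with BH-adjusted p-values.

    For groups a, b with mean ranks Rbar in the pooled ranking of all N
    observations::

        z = (Rbar_a - Rbar_b) / sqrt(V * (1/n_a + 1/n_b))
        V = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1))

    where the sum runs over tie groups of size t.  Two-sided p from the
    standard normal; Benjamini–Hochberg applied over all pairs.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("Dunn's test requires at least two groups")
    pooled = np.concatenate([g.values for g in gs])
    n = np.array([len(g.values) for g in gs])
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    offset = 0
    for g in gs:
        mean_ranks.append(float(np.mean(ranks[offset : offset + len(g.values)])))
        offset += len(g.values)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    V = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    pairs = list(itertools.combinations(range(len(gs)), 2))
    zs, praw = [], []
    for i, j in pairs:
        se = math.sqrt(V * (1.0 / n[i] + 1.0 / n[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        zs.append(z)
        praw.append(2.0 * sps.norm.sf(abs(z)))
    padj = bh_adjust(praw)
    return [
        PairwiseResult(
            pair=(gs[i].label, gs[j].label), z=zs[k], p_raw=praw[k], p_adj=padj[k]
        )
        for k, (i, j) in enumerate(pairs)
    ]


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in adj]


def two_sided_t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    equal_var: bool = False,
) -> TestResult:
    """Two-sided t-test; Welch (unequal variances) unless ``equal_var``.

    Degenerate zero-variance inputs with differing means return an
    infinite statistic with p = 0 and a diagnostic note.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult(statistic=0.0, df=a.size + b.size - 2, p=1.0)
        return TestResult(
            statistic=math.inf,
            df=a.size + b.size - 2,
            p=0.0,
            note="zero within-group variance; statistic unbounded",
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(statistic=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def group_comparison_table(
    metric_values: Sequence, *, alpha: float = 0.05
) -> pd.DataFrame:
    """Omnibus K–W plus Dunn pairwise rows for one metric, as a table.

    Mirrors the reporting pattern used throughout the analyses: Dunn
    post-hocs are reported only when the omnibus test is significant at
    ``alpha``, but rows for all pairs are still included for audit.
    """
    gs = _as_groups(metric_values)
    kw = kruskal_wallis(gs)
    rows = [
        {
            "test": "kruskal_wallis",
            "pair": "",
            "statistic": kw.statistic,
            "df": kw.df,
            "p_raw": kw.p,
            "p_adj": math.nan,
            "significant_omnibus": kw.p < alpha,
        }
    ]
    for r in dunn_test(gs):
        rows.append(
            {
                "test": "dunn",
                "pair": f"{r.pair[0]}|{r.pair[1]}",
                "statistic": r.z,
                "df": math.nan,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant_omnibus": kw.p < alpha,
            }
        )
    return pd.DataFrame(rows)
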