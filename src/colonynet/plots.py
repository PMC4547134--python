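"""Minimal matplotlib hooks for the three standard figures.

Deliberately thin: each function draws one axes from the tidy tables
the pipeline writes and returns it, leaving styling to the caller.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from colonynet.movement import GridSpec


def budget_barplot(budgets: pd.DataFrame, colony: str, ax=None):
    """Mean +/- sd percent time-budget per class dyad (one colony).

    Expects the aggregate table from ``nightly_budget_table``.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    sub = budgets[budgets.colony == colony]
    labels = [f"{r.class_a}-{r.class_b}" for r in sub.itertuples()]
    x = np.arange(len(labels))
    ax.bar(x - 0.2, sub.mean_pct_of_a, 0.4,
           yerr=sub.sd_pct_of_a.fillna(0), label="% of first class", capsize=2)
    ax.bar(x + 0.2, sub.mean_pct_of_b, 0.4,
           yerr=sub.sd_pct_of_b.fillna(0), label="% of second class", capsize=2)
    ax.set_xticks(x, labels, rotation=45, ha="right")
    ax.set_ylabel("% of time budget in trophallaxis")
    ax.set_title(f"colony {colony}")
    ax.legend(frameon=False)
    return ax


def residence_heatmap(rmap: dict, grid: GridSpec, group: str, ax=None):
    """Per-cell residence (ant-seconds) for one movement group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    rows = max(r for r, _ in grid.cells) + 1
    cols = max(c for _, c in grid.cells) + 1
    img = np.full((rows, cols), np.nan)
    for (r, c) in grid.cells:
        img[r, c] = 0.0
    for (r, c), s in rmap.get(group, {}).items():
        img[r, c] = s
    im = ax.imshow(img, origin="upper", interpolation="nearest")
    ax.figure.colorbar(im, ax=ax, label="ant-seconds")
    ax.set_title(f"residence: {group}")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def spread_curve_plot(curves: pd.DataFrame, colony: str, ax=None):
    """Mean fraction of the network reached over time, by seed class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    sub = curves[curves.colony == colony]
    for label, grp in sub.groupby("seed_class"):
        ax.plot(grp.t_s, grp.mean_fraction, label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean fraction reached")
    ax.set_ylim(0, 1)
    ax.set_title(f"colony {colony}")
    ax.legend(frameon=False, fontsize=8)
    return ax
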