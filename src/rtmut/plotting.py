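"""Plot helpers for the spectrum and burden analyses."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .spectrum_test import ControlNullModel


def plot_null_distances(
    null: ControlNullModel,
    observed: Mapping[str, float] | None = None,
    ax=None,
    bins: int = 50,
):
    """Histogram of bootstrap null distances with observed distances overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.hist(null.null_distances, bins=bins, color="steelblue", alpha=0.7,
            label="bootstrap null")
    if observed:
        for name, d in observed.items():
            ax.axvline(d, color="firebrick", linestyle="--", linewidth=1)
            ax.text(d, ax.get_ylim()[1] * 0.95, name, rotation=90,
                    va="top", ha="right", fontsize=7)
    ax.set_xlabel("Euclidean distance to control centroid")
    ax.set_ylabel("bootstrap replicates")
    ax.set_title(f"RT state: {null.rt_state}")
    ax.legend(frameon=False)
    return ax


def plot_burden_boxplots(
    table: pd.DataFrame,
    expanded_members: Sequence[str],
    groups: Sequence[str],
    assay: str = "sbs",
    states: Sequence[str] = ("early", "late"),
    ax=None,
):
    """Boxplots of expanded-control burden with group replicates as dots."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.5 * len(states), 4))
    ctrl = table[table["sample"].isin(expanded_members)]
    data = [ctrl[f"{assay}_{s}"].to_numpy() for s in states]
    ax.boxplot(data, tick_labels=list(states))
    colors = plt.cm.tab10(np.linspace(0, 1, max(len(groups), 1)))
    for gi, grp in enumerate(groups):
        sub = table[table["group"] == grp]
        for si, state in enumerate(states):
            y = sub[f"{assay}_{state}"].to_numpy()
            x = np.full(y.size, si + 1) + np.linspace(-0.15, 0.15, max(y.size, 1))[: y.size]
            ax.scatter(x, y, color=colors[gi], zorder=3, s=25, label=grp if si == 0 else None)
    ax.set_ylabel(f"{assay.upper()} mutation count")
    if len(groups):
        ax.legend(frameon=False, fontsize=8)
    return ax
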