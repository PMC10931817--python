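"""Best-effort figure helpers in the style of the study's panels."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["side_count_boxplot", "volume_scatter", "position_map"]

_AGE_COLORS = {"young_adult": "#5b8dd9", "quiet_aged": "#b3793b"}


def side_count_boxplot(cohort: pd.DataFrame, ax: Optional[plt.Axes] = None):
    """Boxplots of per-animal mean counts, modiolar vs pillar, by age."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    positions, labels = [], []
    pos = 0
    for age, asub in cohort.groupby("age_group", sort=True):
        for side, ssub in asub.groupby("side", sort=True):
            vals = ssub["mean_count"].dropna().values
            if not len(vals):
                continue
            bp = ax.boxplot(
                [vals], positions=[pos], widths=0.7, patch_artist=True,
                showmeans=True,
            )
            bp["boxes"][0].set_facecolor(_AGE_COLORS.get(age, "grey"))
            bp["boxes"][0].set_alpha(0.6 if side == "pillar" else 0.9)
            positions.append(pos)
            labels.append(f"{age}\n{side}")
            pos += 1
        pos += 0.5
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("synapses per IHC")
    return ax


def volume_scatter(pairs: pd.DataFrame, ax: Optional[plt.Axes] = None):
    """Pre vs post normalized volume scatter (log axes)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(
        pairs["pre_norm_volume"], pairs["post_norm_volume"],
        s=6, alpha=0.4, linewidths=0,
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("normalized presynaptic volume")
    ax.set_ylabel("normalized postsynaptic volume")
    return ax


def position_map(pairs: pd.DataFrame, ax: Optional[plt.Axes] = None):
    """Normalized (modiolar–pillar, top–bottom) scatter of pair centres."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pairs["u_mp"], pairs["u_tb"], s=6, alpha=0.4, linewidths=0)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(1, 0)  # top of the cell at the top of the panel
    ax.set_xlabel("modiolar ← position → pillar")
    ax.set_ylabel("top ← position → bottom")
    return ax
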