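"""Figure export: excitability time courses and state-space trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mep import CUE_BIN_LABELS, RESPONSE_BIN_LABELS
from .statespace import CANONICAL_BINS, participant_trajectories

TASK_COLORS = {"SST": "tab:red", "GoOnly": "tab:blue"}


def _group_curve(binned: pd.DataFrame, labels) -> pd.DataFrame:
    per = (
        binned.groupby(["task", "coil", "bin_label"], observed=True)["mean_normalized_mep"]
        .agg(["mean", "sem"])
        .reset_index()
    )
    per["bin_label"] = pd.Categorical(per["bin_label"], categories=labels, ordered=True)
    return per.sort_values("bin_label")


def plot_excitability_timecourses(cue_binned: pd.DataFrame, resp_binned: pd.DataFrame):
    """Mean +/- SE normalized MEP curves, cue-locked (top) and
    response-locked (bottom), one column per coil orientation."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey="row")
    for row, (binned, labels, xlab) in enumerate(
        [
            (cue_binned, CUE_BIN_LABELS, "time after go cue (ms)"),
            (resp_binned, RESPONSE_BIN_LABELS, "time before movement (ms)"),
        ]
    ):
        curve = _group_curve(binned, labels)
        for col, coil in enumerate(("PA120", "AP30")):
            ax = axes[row, col]
            for task, color in TASK_COLORS.items():
                sub = curve[(curve["task"] == task) & (curve["coil"] == coil)]
                x = np.arange(len(sub))
                ax.errorbar(x, sub["mean"], yerr=sub["sem"], color=color, marker="o", label=task)
                ax.set_xticks(np.arange(len(labels)), labels, rotation=45)
            ax.axhline(1.0, color="gray", lw=0.6, ls=":")
            ax.set_title(coil)
            ax.set_xlabel(xlab)
            if col == 0:
                ax.set_ylabel("normalized MEP")
    axes[0, 0].legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_state_space(binned: pd.DataFrame, alignment: str):
    """Group-mean PA x AP trajectory per task with the x = y reference line."""
    trajs = participant_trajectories(binned, alignment)
    fig, ax = plt.subplots(figsize=(5, 5))
    labels = CANONICAL_BINS[alignment]
    for task, color in TASK_COLORS.items():
        pts = [t.points for (pid, tk), t in trajs.items() if tk == task]
        if not pts:
            continue
        allp = pd.concat(pts).groupby("bin_label", observed=True).mean()
        allp = allp.reindex([b for b in labels if b in allp.index])
        ax.plot(allp["pa"], allp["ap"], "-o", color=color, label=task, ms=4)
        ax.plot(allp["pa"].iloc[0], allp["ap"].iloc[0], "*", color=color, ms=14)
    lims = ax.get_xlim() + ax.get_ylim()
    lo, hi = min(lims), max(lims)
    ax.plot([lo, hi], [lo, hi], "--", color="gray", lw=0.8)
    ax.set_xlabel("normalized PA$_{120}$ MEP")
    ax.set_ylabel("normalized AP$_{30}$ MEP")
    ax.set_title(alignment.replace("_", "-"))
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
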