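"""Static plots for fitted results (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["similarity_heatmap", "score_boxplot"]


def similarity_heatmap(similarity: pd.DataFrame, cluster_labels: pd.Series = None, ax=None):
    """Heatmap of pairwise program similarities, ordered by cluster."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    sim = similarity
    if cluster_labels is not None and len(cluster_labels) == len(similarity):
        order = cluster_labels.sort_values(kind="stable").index
        sim = similarity.loc[order, order]
    im = ax.imshow(sim.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(sim)), sim.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(sim)), sim.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="|Pearson r| of loadings")
    ax.set_title("Program loading similarity")
    return ax


def score_boxplot(sensitivity_table: pd.DataFrame, ax=None):
    """Per-experiment boxplots of sensitivity scores, split by class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups, labels = [], []
    for exp_id, sub in sensitivity_table.groupby("experiment_id", sort=True):
        for cls in ("less_sensitive", "unlabeled", "more_sensitive"):
            vals = sub.loc[sub["sens_class"] == cls, "cis_sen_score"].to_numpy()
            if vals.size:
                groups.append(vals)
                labels.append(f"{exp_id}\n{cls.split('_')[0]}")
    ax.boxplot(groups, tick_labels=labels)
    ax.tick_params(axis="x", labelsize=6, rotation=90)
    ax.set_ylabel("CisSenScore (log2 top/bottom counts)")
    ax.set_title("Per-cell sensitivity scores by class")
    return ax
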