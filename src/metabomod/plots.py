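"""Plot helpers for the main result objects (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_roc", "plot_enrichment", "plot_cross_omics"]


def plot_roc(report, ax=None):
    """ROC curve with the Youden cutoff marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    curve = report.curve
    fpr = 1 - curve.specificity
    order = np.argsort(fpr, kind="stable")
    ax.plot(fpr[order], curve.sensitivity[order], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    y = report.youden
    ax.scatter([1 - y["specificity"]], [y["sensitivity"]], c="crimson", zorder=3)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {report.auc:.3f}, J = {y['J']:.3f}")
    return ax


def plot_enrichment(table: pd.DataFrame, module: str | None = None, top: int = 10, ax=None):
    """Horizontal bar plot: bar length = pathway ratio, color = p gradient,
    bars ordered by p."""
    t = table
    if module is not None and "module" in t.columns:
        t = t[t["module"] == module]
    t = t.nsmallest(top, "p").iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.4 * max(len(t), 3) + 1))
    colors = plt.cm.viridis_r(np.clip(-np.log10(t["p"].to_numpy() + 1e-300) / 10, 0, 1))
    ax.barh(t["pathway"], t["ratio"], color=colors)
    ax.set_xlabel("pathway members / module size")
    if module:
        ax.set_title(module)
    return ax


def plot_cross_omics(result, ax=None):
    """Heatmap of metabolite-module x protein-module correlations; cells with
    p below the significance threshold are annotated."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    r = result.r.astype(float)
    im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=90)
    ax.set_yticks(range(r.shape[0]), r.index)
    sig = set(
        zip(result.pairs[result.pairs["significant"]]["metabolite_module"],
            result.pairs[result.pairs["significant"]]["protein_module"])
    )
    for i, mi in enumerate(r.index):
        for j, pj in enumerate(r.columns):
            if (mi, pj) in sig:
                ax.text(j, i, f"{r.iloc[i, j]:.2f}", ha="center", va="center", fontsize=7)
    plt.colorbar(im, ax=ax, label="Pearson r")
    return ax
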