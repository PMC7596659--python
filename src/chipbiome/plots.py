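"""Publication-style figures for pipeline artifacts (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import ClassifierReport
from .diversity import OrdinationResult

GROUP_COLORS = {"ALL": "#e8638c", "NC": "#4a7fd4"}


def _group_color(groups: pd.Series) -> list[str]:
    return [GROUP_COLORS.get(g, "#888888") for g in groups]


def ordination_plot(result: OrdinationResult, groups: pd.Series, path: str | Path) -> None:
    """Scatter of the first two ordination axes colored by group."""
    coords = result.coordinates.iloc[:, :2]
    groups = groups.loc[coords.index]
    fig, ax = plt.subplots(figsize=(5, 4))
    for g in sorted(groups.unique()):
        sub = coords[groups == g]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=18, label=g, color=GROUP_COLORS.get(g))
    labels = list(coords.columns)
    if result.method == "PCoA" and result.proportion_explained is not None:
        labels = [
            f"{c} ({100 * v:.1f}%)"
            for c, v in zip(coords.columns, result.proportion_explained[:2])
        ]
    title = result.method
    if result.stress is not None:
        title += f" (stress = {result.stress:.2f})"
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def lefse_barplot(results: pd.DataFrame, path: str | Path) -> None:
    """Horizontal LDA-score bars, signed by enriched group."""
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(results))))
    if results.empty:
        ax.text(0.5, 0.5, "no taxa passed", ha="center", va="center")
    else:
        sub = results.sort_values("lda_score")
        colors = [GROUP_COLORS.get(g, "#888888") for g in sub["enriched_group"]]
        ax.barh(sub["taxon"], sub["lda_score"], color=colors)
        ax.set_xlabel("LDA score (log10)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_plot(reports: dict[str, ClassifierReport], path: str | Path) -> None:
    """ROC curves (one per rank) with AUC and CI in the legend."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for rank, rep in reports.items():
        ax.plot(
            rep.curve["fpr"],
            rep.curve["tpr"],
            label=f"{rank}: AUC={rep.auc:.3f} ({rep.auc_ci_low:.3f}-{rep.auc_ci_high:.3f})",
        )
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def importance_plot(importance: pd.Series, path: str | Path) -> None:
    """Top discriminant taxa by mean decrease in impurity."""
    fig, ax = plt.subplots(figsize=(5, max(2, 0.3 * len(importance))))
    importance.iloc[::-1].plot.barh(ax=ax, color="#4a7fd4")
    ax.set_xlabel("Mean decrease in impurity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_heatmap(table: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    """Species x cytokine heatmap restricted to significant correlations."""
    keep_species = table.loc[table["p_value"] < alpha, "species"].unique()
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(keep_species))))
    if len(keep_species) == 0:
        ax.text(0.5, 0.5, "no significant correlations", ha="center", va="center")
    else:
        grid = table[table["species"].isin(keep_species)].pivot(
            index="species", columns="cytokine", values="rho"
        )
        im = ax.imshow(grid.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
        ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=45, ha="right")
        ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=7)
        stars = table[table["species"].isin(keep_species)].pivot(
            index="species", columns="cytokine", values="stars"
        )
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                s = stars.iloc[i, j]
                if isinstance(s, str) and s:
                    ax.text(j, i, s, ha="center", va="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
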