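"""Figure export: volcano plot, similarity heatmap, 3D projection scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def volcano_plot(table: pd.DataFrame, path, delta_threshold: float = 6.0,
                 p_threshold: float = 0.025, title: str = "") -> None:
    """Scatter of delta vs -log10 p with the significance bounds drawn."""
    fig, ax = plt.subplots(figsize=(6, 5))
    hit = table["volcano_hit"].to_numpy(dtype=bool)
    ax.scatter(table.loc[~hit, "delta"], table.loc[~hit, "neg_log10_p"],
               s=8, c="0.6", label="not significant")
    ax.scatter(table.loc[hit, "delta"], table.loc[hit, "neg_log10_p"],
               s=12, c="crimson", label="volcano hit")
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.8, c="k")
    for x in (delta_threshold, -delta_threshold):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel(r"$\log_2$ affinity difference")
    ax.set_ylabel(r"$-\log_{10}$ permutation $p$")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def similarity_heatmap(mat: pd.DataFrame, path, title: str = "Jaccard similarity") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mat.to_numpy() * 100.0, cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(mat.index)), mat.index)
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            ax.text(j, i, f"{mat.iloc[i, j] * 100:.1f}", ha="center", va="center",
                    fontsize=7, color="w")
    fig.colorbar(im, label="Jaccard (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def projection_scatter3d(result, path, title: str = "Uncentered PCA") -> None:
    """3D scatter of the first three component scores, coloured by cluster."""
    scores = result.scores
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 components for a 3D scatter")
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    colors = (result.cluster_labels.to_numpy()
              if result.cluster_labels is not None else "0.4")
    ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], scores.iloc[:, 2],
               s=8, c=colors, cmap="tab10")
    # Loadings drawn as arrows from the origin, scaled to the score cloud.
    scale = 0.8 * np.abs(scores.iloc[:, :3].to_numpy()).max()
    for cond, row in result.loadings.iloc[:, :3].iterrows():
        v = row.to_numpy()
        v = v / (np.linalg.norm(v) or 1.0) * scale
        ax.quiver(0, 0, 0, *v, color="r", lw=1.2)
        ax.text(*v, cond, color="r", fontsize=8)
    ev = result.explained_fraction
    ax.set_xlabel(f"PC1 ({ev[0] * 100:.0f}%)")
    ax.set_ylabel(f"PC2 ({ev[1] * 100:.0f}%)")
    ax.set_zlabel(f"PC3 ({ev[2] * 100:.0f}%)" if len(ev) > 2 else "PC3")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
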