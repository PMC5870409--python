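"""Figure outputs: Fst heatmap, LD triangle and bifurcation diagrams."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .bifurcation import BifurcationNode, BifurcationTree
from .ld import HaplotypePanel, pairwise_ld_table

__all__ = ["fst_heatmap", "ld_triangle", "bifurcation_figure", "cline_figure"]


def fst_heatmap(mean_fst, path: str | Path) -> None:
    """Population x population differentiation, grey (proximal) to red
    (distal)."""
    pops = list(mean_fst.index)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(pops), 1 + 0.6 * len(pops)))
    im = ax.imshow(mean_fst.to_numpy(), cmap="Reds", vmin=0)
    ax.set_xticks(range(len(pops)), pops, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(pops)), pops, fontsize=7)
    fig.colorbar(im, ax=ax, label="mean pairwise Fst")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ld_triangle(panel: HaplotypePanel, path: str | Path,
                measure: str = "r_squared") -> None:
    """Haploview-style rotated triangle of pairwise LD."""
    table = pairwise_ld_table(panel)
    m = panel.n_markers
    idx = {name: i for i, name in enumerate(panel.markers)}
    mat = np.full((m, m), np.nan)
    for _, row in table.iterrows():
        i, j = idx[row["marker_i"]], idx[row["marker_j"]]
        mat[i, j] = mat[j, i] = row[measure]
    fig, ax = plt.subplots(figsize=(0.5 * m + 2, 0.3 * m + 2))
    for i in range(m):
        for j in range(i + 1, m):
            # rotate the (i, j) cell 45 degrees below the marker axis
            x = (i + j) / 2.0
            y = -(j - i) / 2.0
            v = mat[i, j]
            color = plt.cm.Reds(0.0 if np.isnan(v) else v)
            ax.add_patch(plt.Polygon(
                [(x, y + 0.5), (x + 0.5, y), (x, y - 0.5), (x - 0.5, y)],
                facecolor=color, edgecolor="white", linewidth=0.3,
            ))
    ax.set_xlim(-1, m)
    ax.set_ylim(-m / 2 - 1, 1)
    ax.set_xticks(range(m), panel.markers, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(f"pairwise {measure}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _draw_tree(ax, tree: BifurcationTree, sign: int, y0: float,
               scale: float) -> None:
    """Recursive layout: x = signed depth, branch width proportional to
    haplotype count."""

    def layout(node: BifurcationNode, x: float, y: float) -> None:
        kids = sorted(node.children.items())
        if not kids:
            return
        n_k = len(kids)
        offsets = np.linspace(-0.4, 0.4, n_k) if n_k > 1 else [0.0]
        for (_, child), dy in zip(kids, offsets):
            cy = y + dy * (0.8 ** child.depth)
            ax.plot(
                [x, x + sign], [y, cy],
                linewidth=max(0.5, scale * child.count), color="k",
                solid_capstyle="round",
            )
            layout(child, x + sign, cy)

    ax.plot(0, y0, "o", markerfacecolor="white", markeredgecolor="k",
            markersize=8, zorder=3)
    layout(tree.root, 0.0, y0)


def bifurcation_figure(
    derived_proximal: BifurcationTree,
    derived_distal: BifurcationTree,
    ancestral_proximal: BifurcationTree,
    ancestral_distal: BifurcationTree,
    path: str | Path,
) -> None:
    """Two-panel bidirectional bifurcation diagram (derived allele on top,
    ancestral below), line thickness proportional to haplotype count."""
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for ax, (prox, dist, label) in zip(
        axes,
        [(derived_proximal, derived_distal, "derived"),
         (ancestral_proximal, ancestral_distal, "ancestral")],
    ):
        n = max(prox.root_count, 1)
        scale = 4.0 / n
        _draw_tree(ax, prox, sign=-1, y0=0.0, scale=scale)
        _draw_tree(ax, dist, sign=+1, y0=0.0, scale=scale)
        ax.set_ylabel(f"{label} ({prox.root_count})")
        ax.set_yticks([])
    axes[-1].set_xlabel("markers from core (proximal < 0 < distal)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cline_figure(maf_table, path: str | Path) -> None:
    """MAF per SNP along the ordered population axis."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for snp in maf_table.columns:
        ax.plot(range(len(maf_table.index)), maf_table[snp], marker="o",
                label=str(snp))
    ax.set_xticks(range(len(maf_table.index)), list(maf_table.index),
                  rotation=45, ha="right")
    ax.set_ylabel("MAF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
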