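"""Static matplotlib renderings of the pipeline's tables.

Every figure is drawn from an already-computed table; nothing here
recomputes statistics. All functions write a PNG and return its path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def library_sizes(lib: pd.Series, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(lib)), lib.to_numpy(), color="steelblue")
    ax.set_xticks(range(len(lib)), lib.index, rotation=90, fontsize=7)
    ax.set_ylabel("library size")
    return _save(fig, path)


def signal_boxplot(signal: pd.DataFrame, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([signal[c].to_numpy() for c in signal.columns], showfliers=False)
    ax.set_xticks(range(1, signal.shape[1] + 1), signal.columns, rotation=90, fontsize=7)
    ax.set_ylabel("log2 CPM")
    return _save(fig, path)


def mds_plot(coords: pd.DataFrame, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords["x"], coords["y"], s=20, color="steelblue")
    for name, row in coords.iterrows():
        ax.annotate(str(name), (row["x"], row["y"]), fontsize=7)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    return _save(fig, path)


def updown_bars(updown: pd.DataFrame, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(updown))
    ax.bar(x - 0.2, updown["n_up"], width=0.4, color="firebrick", label="up")
    ax.bar(x + 0.2, updown["n_down"], width=0.4, color="navy", label="down")
    ax.set_xticks(x, updown["contrast"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("genes")
    ax.legend()
    return _save(fig, path)


def scatter_table(tbl: pd.DataFrame, xlab: str, ylab: str, path: Path) -> Path:
    """MA or volcano plot from a coordinate table with color/marker columns."""
    fig, ax = plt.subplots(figsize=(5, 5))
    dots = tbl[tbl["marker"] == "dot"]
    cross = tbl[tbl["marker"] == "cross"]
    ax.scatter(dots["x"], dots["y"], s=4, c=list(dots["color"]), marker=".")
    if len(cross):
        ax.scatter(cross["x"], cross["y"], s=12, c=list(cross["color"]), marker="x")
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    return _save(fig, path)


def heatmap(matrix: pd.DataFrame, path: Path, cmap: str = "RdBu_r") -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    if matrix.shape[0] <= 60:
        ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    else:
        ax.set_yticks([])
    fig.colorbar(im, ax=ax)
    return _save(fig, path)


def cluster_profiles(
    matrix: pd.DataFrame, assignment: pd.Series, path: Path
) -> Path:
    ks = sorted(assignment.unique())
    ncol = min(3, len(ks))
    nrow = int(np.ceil(len(ks) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for ax in axes.flat[len(ks):]:
        ax.axis("off")
    for ax, k in zip(axes.flat, ks):
        sub = matrix.loc[assignment[assignment == k].index]
        for _, row in sub.iterrows():
            ax.plot(row.to_numpy(), color="grey", alpha=0.3, lw=0.5)
        ax.plot(sub.mean(axis=0).to_numpy(), color="firebrick", lw=1.5)
        ax.set_title(f"cluster {k} (n={len(sub)})", fontsize=8)
        ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=5)
    return _save(fig, path)


def network_plot(layout: dict[str, tuple[float, float]], kinds: dict[str, str],
                 colors: dict[str, str], edges, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 5))
    for u, v in edges:
        if u in layout and v in layout:
            ax.plot(
                [layout[u][0], layout[v][0]],
                [-layout[u][1], -layout[v][1]],
                color="lightgrey",
                lw=0.4,
                zorder=1,
            )
    for nid, (x, y) in layout.items():
        is_contrast = kinds.get(nid) == "contrast"
        ax.scatter(
            [x],
            [-y],
            s=60 if is_contrast else 10,
            c=[colors.get(nid, "black")],
            zorder=2,
        )
        if is_contrast:
            ax.annotate(nid, (x, -y), fontsize=7)
    ax.axis("off")
    return _save(fig, path)
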