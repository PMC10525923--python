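"""Figure rendering: enrichment bars, age trajectories, PCA scatter, volcano.

Thin matplotlib wrappers over the analysis tables; every function writes to a
file path (SVG/PNG by extension) and returns it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def enrichment_bars(enrichment: pd.DataFrame, path: str | Path,
                    column: str = "count_share", ylabel: str = "% of lipids") -> Path:
    fig, ax = plt.subplots(figsize=(7, 4))
    enrichment[column].plot.bar(ax=ax, color="#4878a8")
    ax.set_ylabel(ylabel)
    ax.set_xlabel("")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def age_trajectory_lines(trajectory: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for group, sub in trajectory.groupby("group"):
        sub = sub.sort_values("age")
        ax.plot(sub["age"], sub["mean_total"], marker="o", ms=3, lw=1, label=group)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("normalized group abundance")
    ax.legend(fontsize=6, ncol=2, frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def pca_scatter(scores: pd.DataFrame, labels: pd.Series, pair: tuple[int, int],
                explained: np.ndarray, path: str | Path) -> Path:
    cx, cy = f"PC{pair[0]}", f"PC{pair[1]}"
    fig, ax = plt.subplots(figsize=(5, 5))
    for value, sub in scores.groupby(labels.loc[scores.index]):
        ax.scatter(sub[cx], sub[cy], label=str(value), s=35, alpha=0.85,
                   edgecolor="k", linewidth=0.4)
    ax.set_xlabel(f"{cx} ({100 * explained[pair[0] - 1]:.1f}%)")
    ax.set_ylabel(f"{cy} ({100 * explained[pair[1] - 1]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def volcano_plot(volcano: pd.DataFrame, q: float, path: str | Path) -> Path:
    """-log10 p versus log2 fold change with the raw-0.05 and BH-q dashed lines."""
    sub = volcano.dropna(subset=["log2fc", "p_raw"])
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = np.where(sub["significant"], "#c0392b",
                      np.where(sub["suggestive"], "#e67e22", "#7f8c8d"))
    ax.scatter(sub["log2fc"], -np.log10(sub["p_raw"]), c=colors, s=18, alpha=0.8)
    ax.axhline(-np.log10(0.05), ls="--", lw=0.8, color="k")
    # BH boundary on the raw-p axis: largest raw p still called significant
    sig_p = sub.loc[sub["significant"], "p_raw"]
    if len(sig_p):
        ax.axhline(-np.log10(sig_p.max()), ls="--", lw=0.8, color="#c0392b")
    ax.set_xlabel("log2 fold change (case / control)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
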