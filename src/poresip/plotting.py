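"""Figures for evaluation reports and posterior interpretation."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import FdrPoint

_CLASS_COLORS = {0: "tab:orange", 1: "tab:blue"}


def plot_error_response_curves(
    curves: Mapping[int, np.ndarray], path: str, title: str = "Error response"
) -> None:
    """Per-class error response vs normalized read rank.

    Reads are ordered by increasing distance to their true class; the
    fraction of the x-axis below the 0.5 line is the correct-classification
    rate of that class.
    """
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for cls, curve in curves.items():
        frac_correct = float(np.mean(curve[:, 1] < 0.5)) if curve.size else float("nan")
        ax.plot(
            curve[:, 0], curve[:, 1],
            color=_CLASS_COLORS.get(cls, "k"),
            label=f"class {cls} ({frac_correct:.2f} correct)",
        )
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("reads, ordered by distance to true class (normalized)")
    ax.set_ylabel("error response")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fdr_curve(curve: Sequence[FdrPoint], path: str, title: str = "FDR vs cutoff") -> None:
    """False discovery rate and classified fraction against the cutoff."""
    cutoffs = [pt.cutoff for pt in curve]
    fdrs = [np.nan if pt.fdr is None else pt.fdr for pt in curve]
    fracs = [pt.fraction_classified for pt in curve]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(cutoffs, fdrs, color="k", label="FDR")
    ax.set_xlabel("error response cutoff")
    ax.set_ylabel("FDR", color="k")
    ax2 = ax.twinx()
    ax2.plot(cutoffs, fracs, color="tab:blue", label="fraction classified")
    ax2.set_ylabel("fraction of reads classified", color="tab:blue")
    ax2.set_ylim(0, 1.02)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importance_matrix(table: pd.DataFrame, path: str, title: str = "Marginal importance") -> None:
    """Heatmap of per-position nucleotide importance (rows A/C/G/T)."""
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * table.shape[1], 3.2))
    im = ax.imshow(table.values, cmap="viridis", aspect="auto")
    ax.set_xticks(range(table.shape[1]), [str(c) for c in table.columns])
    ax.set_yticks(range(table.shape[0]), list(table.index))
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            ax.text(j, i, f"{table.values[i, j]:.2f}", ha="center", va="center",
                    color="w", fontsize=8)
    ax.set_xlabel("position in k-mer")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
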