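"""Matplotlib rendering of experiment and search-space results."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .signal_model import PARAM_NAMES

__all__ = [
    "boxplot_summaries",
    "heatmap",
    "manifold_scatter",
    "mwf_histogram_overlay",
    "signal_profiles",
]


def _cell_label(labels: dict) -> str:
    parts = []
    for key in ("tissue", "scheme", "bounds", "kfs_true", "swept_param", "swept_value"):
        if key in labels:
            v = labels[key]
            parts.append(f"{v:g}" if isinstance(v, float) else str(v))
    return "/".join(parts) or "cell"


def boxplot_summaries(summaries, param: str, path) -> None:
    """One box per experiment cell for a single estimated parameter."""
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(summaries) + 2), 4))
    data = [s.column(param) for s in summaries]
    ax.boxplot(data, tick_labels=[_cell_label(s.labels) for s in summaries])
    truths = {s.truth.to_array()[PARAM_NAMES.index(param)] for s in summaries}
    for t in truths:
        ax.axhline(t, color="k", linestyle="--", linewidth=0.8)
    ax.set_ylabel(param)
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heatmap(grid_x, grid_y, values, path, xlabel="", ylabel="", log_scale=True,
            marks: Optional[Sequence[tuple[float, float, str]]] = None) -> None:
    """Render an eta grid (projection or cut) as a heat map PNG."""
    fig, ax = plt.subplots(figsize=(5, 4))
    plot_vals = np.log10(np.maximum(values, 1e-12)) if log_scale else values
    im = ax.pcolormesh(grid_x, grid_y, plot_vals.T, shading="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="log10(eta)" if log_scale else "eta")
    if marks:
        for x, y, style in marks:
            ax.plot(x, y, style, markersize=8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def manifold_scatter(embedding, path) -> None:
    """First two embedded components of a degenerate solution set."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(
        embedding.coordinates[:, 0],
        embedding.coordinates[:, 1],
        c=embedding.etas,
        s=8,
        cmap="viridis",
    )
    ax.plot(
        embedding.truth_coordinates[0],
        embedding.truth_coordinates[1],
        "d",
        color="green",
        markersize=10,
        label="truth",
    )
    fig.colorbar(sc, ax=ax, label="eta")
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def mwf_histogram_overlay(summaries, top_solutions, path, bins=40) -> None:
    """SRC estimate histograms against the degenerate-solution spread.

    Grey bars: myelin-water-fraction values of the lowest-residual candidate
    set; coloured steps: SRC estimates per bound set.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(
        top_solutions.column("mwf"),
        bins=bins,
        density=True,
        color="0.7",
        label="low-residual solutions",
    )
    for s in summaries:
        ax.hist(
            s.column("mwf"),
            bins=bins,
            density=True,
            histtype="step",
            linewidth=1.5,
            label=str(s.labels.get("bounds", "SRC")),
        )
    ax.axvline(top_solutions.truth.mwf, color="k", linestyle="--")
    ax.set_xlabel("MWF")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def signal_profiles(signal_vectors, path, labels=None) -> None:
    """Plot one or more labelled signal vectors against flip angle."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, sv in enumerate(signal_vectors):
        name = labels[i] if labels else f"signals {i}"
        for seq in dict.fromkeys(sv.sequences):
            m = sv.mask(seq)
            ax.plot(sv.flip_angles_deg[m], sv.values[m], marker="o", markersize=3,
                    label=f"{name} {seq}")
    ax.set_xlabel("flip angle (deg)")
    ax.set_ylabel("signal (a.u.)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
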