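"""Genome-wide diagnostic plots (LOD scan and coverage scatter)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_lod_track", "plot_coverage"]


def _genome_offsets(df: pd.DataFrame) -> tuple[pd.Series, dict[str, float]]:
    """Cumulative x-offsets so chromosomes plot side by side."""
    offsets: dict[str, float] = {}
    cum = 0.0
    spans = df.groupby("chrom", sort=False)[df.columns[1]].max()
    for chrom, span in spans.items():
        offsets[chrom] = cum
        cum += float(span)
    x = df["chrom"].map(offsets) + df[df.columns[1]]
    return x, offsets


def plot_lod_track(track: pd.DataFrame, path: str | Path, threshold: float = 3.0) -> None:
    """Per-variant LOD across the genome, chromosomes alternating in color."""
    x, offsets = _genome_offsets(track[["chrom", "pos", "lod"]])
    fig, ax = plt.subplots(figsize=(12, 3))
    for i, (chrom, sub) in enumerate(track.groupby("chrom", sort=False)):
        ax.scatter(x[sub.index], sub["lod"], s=2, color="C0" if i % 2 else "k", rasterized=True)
    ax.axhline(threshold, color="k", lw=0.8)
    ax.set_xticks([offsets[c] for c in offsets])
    ax.set_xticklabels(list(offsets), rotation=90, fontsize=6)
    ax.set_ylabel("LOD")
    pools = track.attrs.get("pools")
    if pools:
        ax.set_title(f"{pools[0]} vs {pools[1]}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage(windows: pd.DataFrame, path: str | Path) -> None:
    """Window mean depth across the genome, chromosomes alternating in color."""
    x, offsets = _genome_offsets(windows[["chrom", "start", "mean_depth"]])
    fig, ax = plt.subplots(figsize=(12, 3))
    for i, (chrom, sub) in enumerate(windows.groupby("chrom", sort=False)):
        ax.scatter(x[sub.index], sub["mean_depth"], s=2, color="C2" if i % 2 else "k", rasterized=True)
    ax.set_xticks([offsets[c] for c in offsets])
    ax.set_xticklabels(list(offsets), rotation=90, fontsize=6)
    ax.set_ylabel("window depth")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
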