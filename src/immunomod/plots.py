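"""Minimal figure helpers: KM curves, overlap heatmap, locus profile."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .overlap import OverlapMatrix
from .survival import KMCurve

__all__ = ["km_plot", "overlap_heatmap", "locus_plot"]


def km_plot(curves: Mapping[str, KMCurve], path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.step(curve.times, curve.survival, where="post", label=label)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def overlap_heatmap(om: OverlapMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(om.data.to_numpy(), vmin=0, vmax=1, cmap="Greens")
    ax.set_xticks(range(len(om.module_names)))
    ax.set_xticklabels(om.module_names, rotation=90, fontsize=7)
    ax.set_yticks(range(len(om.module_names)))
    ax.set_yticklabels(om.module_names, fontsize=7)
    fig.colorbar(im, ax=ax, label="gene overlap fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def locus_plot(profile: pd.DataFrame, path: str | Path, region: str = "") -> None:
    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    x = profile["start"] / 1e6
    axes[0].plot(x, profile["neg_log10_p"], marker="o", ms=3, lw=0.8)
    axes[0].set_ylabel("-log10 p")
    axes[1].plot(x, profile["median_a"], marker="o", ms=3, lw=0.8, label="group A")
    axes[1].plot(x, profile["median_b"], marker="o", ms=3, lw=0.8, label="group B")
    axes[1].set_ylabel("median copy number")
    axes[1].set_xlabel("position (Mb)")
    axes[1].legend(frameon=False, fontsize=8)
    for _, row in profile[profile["is_landmark"]].iterrows():
        for ax in axes:
            ax.axvline(row["start"] / 1e6, color="grey", lw=0.6, ls="--")
        axes[0].annotate(row["gene_id"], (row["start"] / 1e6, axes[0].get_ylim()[1]),
                         fontsize=7, rotation=90, va="top")
    if region:
        axes[0].set_title(region)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
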