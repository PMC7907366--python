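"""Headless-safe figures for study outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["boxplot_figure", "fes_figure"]


def boxplot_figure(records_by_condition: dict[str, pd.DataFrame],
                   path: str | Path) -> Path:
    """Aspect-ratio box plot per condition.

    Box edges at the 25/75 % quantiles, whiskers spanning the full
    population range, median line in between.
    """
    fig, ax = plt.subplots(figsize=(4, 4))
    names, samples = [], []
    for name, rec in records_by_condition.items():
        sub = rec[rec["label"].isin(["closed", "open"])] if "label" in rec else rec
        names.append(f"{name}\n(n={len(sub)})")
        samples.append(np.asarray(sub["aspect_ratio"], dtype=float))
    ax.boxplot(samples, tick_labels=names, whis=(0, 100))
    ax.axhline(3.0, color="crimson", lw=0.8, ls="--", label="open threshold R=3")
    ax.set_ylabel("aspect ratio R")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def fes_figure(fes, path: str | Path) -> Path:
    """Free-energy surface heat map over the first two dPCA components."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    xe, ye = fes.bin_edges
    im = ax.pcolormesh(xe, ye, fes.grid.T, cmap="viridis_r")
    fig.colorbar(im, ax=ax, label=r"$\Delta G$ (kJ/mol)")
    ax.set_xlabel("dPC 1")
    ax.set_ylabel("dPC 2")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
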