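"""Manhattan-style incidence plots and MDS scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_incidence(profile: pd.DataFrame, threshold: float | None = None,
                   path: str | Path | None = None):
    """Per-SNP ROH incidence along the genome, chromosomes alternately shaded."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    x0 = 0
    for k, (chrom, grp) in enumerate(profile.groupby("chromosome", sort=False)):
        x = x0 + np.arange(len(grp))
        ax.scatter(x, grp["incidence"], s=3,
                   color="#1f77b4" if k % 2 == 0 else "#8ab4d8", linewidths=0)
        x0 = x[-1] + 1 if len(x) else x0
    if threshold is not None:
        ax.axhline(threshold, color="red", lw=1, label=f"threshold = {threshold:.3g}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("SNP index (by chromosome)")
    ax.set_ylabel("ROH incidence")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_mds(coordinates: pd.DataFrame, populations: pd.Series | None = None,
             path: str | Path | None = None):
    """Scatter of the first two MDS components, colored by population."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if populations is None:
        ax.scatter(coordinates["C1"], coordinates["C2"], s=8)
    else:
        for pop in pd.unique(populations):
            m = (populations == pop).to_numpy()
            ax.scatter(coordinates.loc[m, "C1"], coordinates.loc[m, "C2"],
                       s=8, label=str(pop))
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("MDS component 1")
    ax.set_ylabel("MDS component 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
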