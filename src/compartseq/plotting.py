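"""Small plotting helpers (profiles and replicate PCA)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import COMPARTMENTS


def plot_profiles(profiles: pd.DataFrame, assignments: pd.Series | None = None,
                  log: bool = True, ax=None):
    """Line plot of gene profiles over the ordered compartments.

    Genes sharing a group (via ``assignments``) share a color.  NE spans
    orders of magnitude, so a log scale is the default.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(len(profiles.columns))
    groups = assignments.reindex(profiles.index).fillna("none") if assignments is not None else None
    palette = {}
    for gene in profiles.index:
        color = None
        if groups is not None:
            gid = groups[gene]
            if gid not in palette:
                palette[gid] = f"C{len(palette) % 10}"
            color = palette[gid]
        ax.plot(x, profiles.loc[gene], marker="o", label=gene, color=color, alpha=0.8)
    ax.set_xticks(x, list(profiles.columns))
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("lens compartment")
    ax.set_ylabel("NE")
    if len(profiles) <= 12:
        ax.legend(fontsize="x-small")
    return ax


def plot_replicate_pca(qc, ax=None):
    """Scatter of samples in PC1/PC2, colored by compartment."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    coords = qc.coordinates
    comps = [s.split("_")[0] for s in coords.index]
    colors = {c: f"C{i}" for i, c in enumerate(COMPARTMENTS)}
    for s, c in zip(coords.index, comps):
        ax.scatter(coords.iloc[:, 0][s], coords.iloc[:, 1][s] if coords.shape[1] > 1 else 0,
                   color=colors.get(c, "k"), label=c)
        ax.annotate(s, (coords.iloc[:, 0][s],
                        coords.iloc[:, 1][s] if coords.shape[1] > 1 else 0),
                    fontsize="x-small")
    ax.set_xlabel(f"PC1 ({qc.explained_variance_ratio[0]:.0%})")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({qc.explained_variance_ratio[1]:.0%})")
    return ax
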