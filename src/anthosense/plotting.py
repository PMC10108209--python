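"""Schematic plots: discrimination sigmoid with pairwise means, and the
volatile-profile dendrogram. Kept deliberately minimal."""

from __future__ import annotations

import numpy as np

from .discrimination import DiscriminationModel
from .volatilomics import Dendrogram

__all__ = ["plot_discrimination_curve", "plot_dendrogram"]


def plot_discrimination_curve(model: DiscriminationModel, cells=None,
                              v_max: float | None = None, path=None):
    """Sigmoid over color distance; optional part-pair means with SE bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if v_max is None:
        v_max = 0.4 if model.form == "logistic4" else 0.1
    v = np.linspace(0.0, v_max, 400)
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(v, model(v), lw=2)
    ax.axhline(0.5, ls="--", color="grey", lw=0.8)
    if cells is not None:
        for c in cells:
            ax.errorbar([getattr(c, "distance", np.nan)], [c.mean],
                        yerr=[c.se], fmt="o", capsize=3)
    ax.set_xlabel("color distance V")
    ax.set_ylabel("P(correct discrimination)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_dendrogram(dend: Dendrogram, path=None):
    """Ward dendrogram of volatile profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    scipy_dendrogram(dend.linkage_matrix, labels=dend.labels, ax=ax)
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
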