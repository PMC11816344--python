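"""Minimal plotting helpers (Kaplan–Meier curves, similarity heatmap)."""

from __future__ import annotations

import numpy as np

from .survival import KMCurve


def km_plot(curves: dict, ax=None, xlabel="Months", ylabel="Survival probability"):
    """Step plot of one KM curve per labeled group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=str(label))
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax


def similarity_heatmap(sim, labels=None, ax=None):
    """Heatmap of a set-similarity matrix ordered by cluster label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vals = sim.values if hasattr(sim, "values") else np.asarray(sim)
    order = np.argsort(labels) if labels is not None else np.arange(len(vals))
    ax.imshow(vals[np.ix_(order, order)], vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
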