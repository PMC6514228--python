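"""Diagnostic plots for simulation output.

Conditional error curves (bias / MAE / RMSE / SEE against the true-trait
bins) and the items-used / reliability scatter against the final trait
estimate.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .evaluation import ConditionalStats


def _axes(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_conditional_curves(
    stats_by_rule: Mapping[str, ConditionalStats], index: str = "csee", ax=None
):
    """One conditional-index curve per stopping rule over true-theta bins."""
    ax = _axes(ax)
    for label, cs in stats_by_rule.items():
        centers = (cs.bin_edges[:-1] + cs.bin_edges[1:]) / 2
        ax.plot(centers, getattr(cs, f"bin_{index}"), marker="o", label=label)
    ax.set_xlabel(r"true $\theta$")
    ax.set_ylabel(index.upper())
    ax.legend()
    return ax


def plot_items_and_reliability(records: Sequence, ax=None):
    """Items used and per-person reliability vs the final trait estimate."""
    ax = _axes(ax)
    theta = np.array([r.estimate.theta for r in records])
    used = np.array([r.n_items_used for r in records])
    rel = 1.0 - np.array([r.estimate.se for r in records]) ** 2
    ax.scatter(theta, used, s=8, label="items used")
    ax2 = ax.twinx()
    ax2.scatter(theta, rel, s=8, color="tab:orange", label="reliability")
    ax.set_xlabel(r"final $\hat\theta$")
    ax.set_ylabel("items used")
    ax2.set_ylabel("reliability $1 - SE^2$")
    return ax
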