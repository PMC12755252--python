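"""Optional plotting helpers for sweep outputs.

These take the tidy frames produced by :func:`grnswitch.residence.cv_sweep`
and :func:`grnswitch.residence.hybrid_cv_sweep` and return matplotlib
figures; they never show or save anything themselves.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_cv_response", "plot_switching_heatmap"]


def plot_cv_response(df: pd.DataFrame, ax=None):
    """Normalized mean residence time vs delay CV, one line per state."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for state, sub in df.groupby("state"):
        sub = sub.sort_values("cv")
        ax.errorbar(
            sub["cv"], sub["norm_mean"], yerr=sub["norm_se"],
            marker="o", capsize=3, label=str(state),
        )
    ax.axhline(1.0, color="0.6", lw=0.8, ls="--")
    ax.set_xlabel("delay CV")
    ax.set_ylabel("normalized mean residence time")
    ax.legend(title="state", frameon=False)
    return ax.figure


def plot_switching_heatmap(df: pd.DataFrame, ax=None):
    """Normalized mean residence time over the (switching rate, CV) grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    pivot = df.pivot_table(index="r", columns="cv", values="norm_mean")
    mesh = ax.pcolormesh(
        pivot.columns, np.arange(len(pivot.index)), pivot.values, shading="nearest"
    )
    ax.set_yticks(np.arange(len(pivot.index)), [f"{r:g}" for r in pivot.index])
    ax.set_xlabel("sigma / mu (Bernoulli delay CV)")
    ax.set_ylabel("switching rate r")
    ax.figure.colorbar(mesh, ax=ax, label="normalized mean residence time")
    return ax.figure
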