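"""Diagnostic figures: size-density diagrams and warming trajectories."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_thinning_diagram", "plot_trajectories", "plot_k_events"]


def plot_thinning_diagram(periods, line=None, mat_split=None, ax=None):
    """Log-log size-density scatter with optional fitted thinning line.

    ``periods`` needs D_start and N_start; points are coloured by whether the
    plot long-term MAT is above ``mat_split`` (default: dataset mean) when a
    ``mat_longterm`` column exists.  ``line`` is a SelfThinningLine or
    (intercept, slope) pair.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = periods["D_start"].to_numpy()
    n = periods["N_start"].to_numpy()
    if "mat_longterm" in periods:
        split = periods["mat_longterm"].mean() if mat_split is None else mat_split
        warm = periods["mat_longterm"] > split
        ax.scatter(d[~warm], n[~warm], s=8, c="tab:blue", alpha=0.5, label=f"MAT <= {split:.1f} C")
        ax.scatter(d[warm], n[warm], s=8, c="tab:red", alpha=0.5, label=f"MAT > {split:.1f} C")
    else:
        ax.scatter(d, n, s=8, alpha=0.5)
    if line is not None:
        a, s = (line.intercept, line.slope) if hasattr(line, "intercept") else line
        dd = np.geomspace(d.min(), d.max(), 50)
        ax.plot(dd, np.exp(a + s * np.log(dd)), "k-", lw=1.5, label="self-thinning line")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("quadratic mean diameter D (cm)")
    ax.set_ylabel("stocking N (trees/ha)")
    ax.legend(fontsize=8)
    return ax


def plot_trajectories(trajectories: dict, ax=None):
    """Overlay (D, N) trajectories, e.g. baseline vs transient vs permanent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, tr in trajectories.items():
        ax.plot(tr["D"], tr["N"], label=label)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("quadratic mean diameter D (cm)")
    ax.set_ylabel("stocking N (trees/ha)")
    ax.legend(fontsize=8)
    return ax


def plot_k_events(events, slope=None, ax=None):
    """Dead-tree QMD vs live-tree QMD with the 1:1 line and pooled-k fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = events["D_start"].to_numpy()
    y = events["dead_qmd"].to_numpy()
    ax.scatter(x, y, s=10, alpha=0.5)
    lim = np.array([0.0, x.max() * 1.05])
    ax.plot(lim, lim, "k-", lw=1, label="1:1")
    if slope is not None:
        ax.plot(lim, slope * lim, "r-", lw=1.5, label=f"k = {slope:.2f}")
    ax.set_xlabel("live-tree QMD at period start (cm)")
    ax.set_ylabel("dead-tree QMD at period end (cm)")
    ax.legend(fontsize=8)
    return ax
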