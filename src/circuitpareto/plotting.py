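"""Minimal plotting helpers: objective cloud + highlighted Pareto front,
and timecourses.  Figures mirror the standard layout of sensitivity MOO
plots (cloud in a light shade, front emphasized)."""
from __future__ import annotations

import numpy as np

from .pareto import ParetoResult
from .steady_state import Trajectory

__all__ = ["plot_pareto", "plot_trajectory"]


def plot_pareto(result: ParetoResult, ax=None, cloud_kw=None, front_kw=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cloud_kw = {"s": 4, "alpha": 0.25, "color": "tab:blue",
                "label": "sampled", **(cloud_kw or {})}
    front_kw = {"s": 25, "color": "tab:orange", "zorder": 3,
                "label": "Pareto front", **(front_kw or {})}
    obj = result.objectives
    ax.scatter(obj[:, 0], obj[:, 1], **cloud_kw)
    front = result.front_points
    order = np.argsort(front[:, 0])
    ax.plot(front[order, 0], front[order, 1], color=front_kw["color"],
            lw=1, zorder=2)
    ax.scatter(front[:, 0], front[:, 1], **front_kw)
    ax.set_xlabel(result.pair.labels[0])
    ax.set_ylabel(result.pair.labels[1])
    ax.set_title(f"{result.pair} ({result.tradeoff})")
    ax.legend(loc="best")
    return ax


def plot_trajectory(traj: Trajectory, species=("x", "y"), ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for i in range(traj.states.shape[1]):
        label = species[i] if i < len(species) else f"species {i}"
        ax.plot(traj.times, traj.states[:, i], label=label)
    ax.set_xlabel("time (unitless)")
    ax.set_ylabel("concentration (unitless)")
    ax.legend()
    return ax
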