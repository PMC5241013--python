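"""Optional matplotlib figures for the sampling and SAD diagnostics.

matplotlib is imported lazily so the core pipeline has no hard dependency
on it (install the ``plots`` extra).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .sad import SadFit, predict_rad
from .sampling import AccumulationCurve, CoverTrajectory

__all__ = ["plot_accumulation_curve", "plot_cover_trajectories", "plot_whittaker"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_accumulation_curve(curve: AccumulationCurve, ax=None):
    """Mean rarefied richness with a +/-1 sd band against points sampled."""
    ax = _axes(ax)
    ax.plot(curve.n_points, curve.mean_richness, color="C0")
    ax.fill_between(
        curve.n_points,
        curve.mean_richness - curve.sd_richness,
        curve.mean_richness + curve.sd_richness,
        alpha=0.3,
        color="C0",
        linewidth=0,
    )
    ax.set_xlabel("point intercepts")
    ax.set_ylabel("species")
    ax.set_title(f"Species accumulation ({curve.n_replicates} shuffles)")
    return ax


def plot_cover_trajectories(
    trajectories: Sequence[CoverTrajectory], top_n: int = 5, ax=None
):
    """Cumulative FPC in field order; the top_n most abundant are labelled."""
    ax = _axes(ax)
    k = np.arange(1, len(trajectories[0].values) + 1)
    for i, traj in enumerate(trajectories):
        label = traj.species_code if i < top_n else None
        ax.plot(k, traj.values, label=label, alpha=0.9 if label else 0.3,
                color=f"C{i}" if label else "grey")
    ax.set_xlabel("point intercepts (field order)")
    ax.set_ylabel("cumulative cover (%)")
    if top_n:
        ax.legend(fontsize="small")
    return ax


def plot_whittaker(covers: Sequence[float], fit: SadFit, ax=None):
    """Empirical rank-abundance points with the fitted SAD's prediction."""
    ax = _axes(ax)
    x = np.sort(np.asarray(covers, dtype=float)[np.asarray(covers) > 0])[::-1]
    ranks = np.arange(1, x.size + 1)
    ax.semilogy(ranks, x, "o", label="empirical")
    ax.semilogy(ranks, predict_rad(fit, x.size), "-", label=fit.distribution)
    ax.set_xlabel("species rank")
    ax.set_ylabel("cover (%)")
    ax.legend()
    return ax
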