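"""Diagnostic plots: scree curve, SA traces, original-vs-lumped profiles.

matplotlib is an optional dependency; import errors surface only when a plot
is requested.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .linear_model import CompartmentalModel, simulate_matrix_exponential
from .lumping import LumpingPartition, lump_rate_matrix
from .scree import ScreeData

__all__ = ["plot_scree", "plot_sa_trace", "plot_output_comparison"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_scree(scree: ScreeData, cutoff: float = 0.0, ax=None, path: Optional[str] = None):
    """Ranked log10|eigenvalue| with the cutoff line."""
    ax = _axes(ax)
    ranked = scree.ranked_log_abs
    finite = np.where(np.isfinite(ranked), ranked, np.nan)
    ax.plot(np.arange(1, len(ranked) + 1), finite, "o-")
    ax.axhline(cutoff, color="grey", ls="--", lw=1)
    ax.set_xlabel("ranked state number")
    ax.set_ylabel("log10 |eigenvalue|")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def plot_sa_trace(traces, ax=None, path: Optional[str] = None):
    """ARD% (log scale) and temperature against iteration, one panel each."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, axs = plt.subplots(1, 2, figsize=(9, 3.5))
    else:
        axs = ax
    arr = np.asarray([t[-4:] for t in traces], dtype=float)
    it, temp, cur, best = arr.T
    axs[0].semilogy(it, temp)
    axs[0].set_xlabel("iteration")
    axs[0].set_ylabel("temperature")
    axs[1].semilogy(it, np.maximum(cur, 1e-300), alpha=0.6, label="current ARD%")
    axs[1].semilogy(it, np.maximum(best, 1e-300), label="best ARD%")
    axs[1].set_xlabel("iteration")
    axs[1].set_ylabel("ARD%")
    axs[1].legend()
    if path:
        axs[0].figure.savefig(path, bbox_inches="tight")
    return axs


def plot_output_comparison(
    model: CompartmentalModel,
    partition: LumpingPartition,
    times,
    ax=None,
    path: Optional[str] = None,
):
    """Original vs lumped output-state concentration-time profile."""
    ax = _axes(ax)
    t = np.asarray(times, dtype=float)
    orig = simulate_matrix_exponential(model, t).trajectories[model.output_state]
    lumped = lump_rate_matrix(model, partition)
    red = simulate_matrix_exponential(lumped.as_model(), t).trajectories[
        lumped.output_block
    ]
    ax.semilogy(t, np.maximum(orig, 1e-300), label="original")
    ax.semilogy(t, np.maximum(red, 1e-300), "--", label=f"lumped (m={partition.m})")
    ax.set_xlabel("time")
    ax.set_ylabel("output concentration")
    ax.legend()
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
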