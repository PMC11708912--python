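"""Diagnostic plots: degree paths, per-node MDSD, cumulative MDSD.

Hub nodes are drawn with solid lines and non-hubs with dashed lines;
the γ·mean cutoff appears as a solid line on the MDSD panel.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # file output only; no display in pipelines

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .screening import cumulative_mdsd  # noqa: E402

__all__ = ["plot_degree_path", "plot_mdsd", "plot_cumulative_mdsd"]


def _hub_mask(p, hub_ids):
    mask = np.zeros(p, dtype=bool)
    if hub_ids is not None:
        mask[np.asarray(list(hub_ids), dtype=int) - 1] = True
    return mask


def plot_degree_path(degree_path, lambdas=None, hub_ids=None, ax=None):
    """Node degrees against tuning-parameter values, hubs as solid lines."""
    D = degree_path.degrees if hasattr(degree_path, "degrees") else np.asarray(degree_path)
    p, M = D.shape
    if lambdas is None:
        grid = getattr(degree_path, "grid", None)
        lambdas = grid.values if grid is not None and grid.q == 1 else np.arange(M)
    hubs = _hub_mask(p, hub_ids)
    if ax is None:
        _, ax = plt.subplots()
    for i in range(p):
        ax.plot(lambdas, D[i], linestyle="-" if hubs[i] else "--",
                color="tab:red" if hubs[i] else "0.7",
                lw=1.2 if hubs[i] else 0.5, zorder=2 if hubs[i] else 1)
    ax.set_xlabel("tuning parameter")
    ax.set_ylabel("estimated node degree")
    ax.invert_xaxis()  # sparse models first, as paths are usually read
    return ax


def plot_mdsd(result, hub_ids=None, ax=None):
    """Per-node MDSD values with the γ·mean cutoff line."""
    values = result.mdsd
    p = len(values)
    hubs = _hub_mask(p, hub_ids)
    if ax is None:
        _, ax = plt.subplots()
    nodes = np.arange(1, p + 1)
    ax.vlines(nodes[~hubs], 0, values[~hubs], color="0.7", lw=0.5,
              linestyle="--")
    if hubs.any():
        ax.vlines(nodes[hubs], 0, values[hubs], color="tab:red", lw=1.2)
    ax.axhline(result.cutoff, color="k",
               label=f"{result.gamma:g} x mean MDSD")
    ax.set_xlabel("node")
    ax.set_ylabel("MDSD")
    ax.legend(loc="best")
    return ax


def plot_cumulative_mdsd(degree_path, hub_ids=None, ax=None):
    """Running MDSD contribution against estimated node degree per node."""
    cum, D = cumulative_mdsd(degree_path)
    p = D.shape[0]
    hubs = _hub_mask(p, hub_ids)
    if ax is None:
        _, ax = plt.subplots()
    for i in range(p):
        ax.plot(D[i], cum[i], linestyle="-" if hubs[i] else "--",
                color="tab:red" if hubs[i] else "0.7",
                lw=1.2 if hubs[i] else 0.5, zorder=2 if hubs[i] else 1)
    ax.set_xlabel("estimated node degree")
    ax.set_ylabel("cumulative MDSD")
    return ax
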