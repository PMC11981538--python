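"""Minimal plotting: log10 flux heat-map and a layered web diagram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .core import FoodWeb
from .flux import FluxMatrix, flux_matrix_log10
from .trophic import TrophicLevels


def plot_flux_matrix(
    fluxes: FluxMatrix, levels: TrophicLevels | None = None, ax=None
):
    """Weighted interaction matrix on a base-10 log scale, rows/columns by TL."""
    display = flux_matrix_log10(fluxes, levels)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(display.to_numpy(), cmap="viridis", aspect="equal")
    ax.set_xticks(range(len(display.columns)), display.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(display.index)), display.index, fontsize=6)
    ax.set_xlabel("consumer")
    ax.set_ylabel("prey")
    plt.colorbar(im, ax=ax, label="log10 flux")
    return ax


def plot_web_layered(web: FoodWeb, levels: TrophicLevels, ax=None):
    """Simple layered diagram: nodes placed by trophic level, edges upward."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    nodes = web.nodes
    tls = np.array([levels[n] for n in nodes])
    xs = {}
    for level in sorted(set(np.round(tls, 1))):
        members = [n for n, t in zip(nodes, tls) if round(t, 1) == level]
        for k, n in enumerate(sorted(members)):
            xs[n] = (k + 1) / (len(members) + 1)
    pos = {n: (xs[n], levels[n]) for n in nodes}
    for u, v in web.edges:
        ax.annotate(
            "", xy=pos[v], xytext=pos[u],
            arrowprops=dict(arrowstyle="-|>", color="0.6", lw=0.6),
        )
    for n in nodes:
        ax.plot(*pos[n], "o", color="tab:blue", ms=6)
        ax.annotate(n, pos[n], textcoords="offset points", xytext=(3, 3), fontsize=6)
    ax.set_ylabel("trophic level")
    ax.set_xticks([])
    return ax
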