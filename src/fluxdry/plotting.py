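"""Minimal figures: sensitivity-grid heatmaps and slope densities."""

from __future__ import annotations

import numpy as np


def plot_sensitivity_grid(grid, ax=None, vlim=0.6, cmap="RdBu", mark_significant=True):
    """Heatmap of a 10x10 sensitivity grid (SWC deciles on y, VPD on x).

    Significant cells (p < 0.05) get a dot when p-values are present.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(grid.sens, origin="lower", vmin=-vlim, vmax=vlim, cmap=cmap,
                   extent=(0.5, 10.5, 0.5, 10.5))
    if mark_significant and grid.pval is not None:
        sig = np.argwhere(grid.pval < 0.05)
        if len(sig):
            ax.scatter(sig[:, 1] + 1, sig[:, 0] + 1, s=6, c="k")
    ax.set_xlabel("VPD percentile bin")
    ax.set_ylabel("SWC percentile bin")
    ax.set_title(f"{grid.response} sensitivity to {grid.variable}")
    plt.colorbar(im, ax=ax, shrink=0.85)
    return ax


def plot_slope_density(slopes, variable="swc", ax=None):
    """Kernel-free histogram of per-site regression slopes for one variable."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    vals = np.asarray(slopes[variable], dtype=float)
    ax.hist(vals, bins=15, density=True, alpha=0.7)
    ax.axvline(vals.mean(), color="k", lw=1)
    ax.set_xlabel(f"standardized {variable} slope")
    ax.set_ylabel("density")
    return ax
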