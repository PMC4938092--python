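"""Figures: aggregate kernel bands and the 2-D PCA scatter."""

from __future__ import annotations

import numpy as np

from .summary import KernelTable, PCAProjection, aggregate_band

_COLORS = {"self_self": "tab:red", "self_partner": "tab:green", "self_other": "tab:blue"}


def plot_aggregate_bands(kt: KernelTable, ax=None, group_by: str = "relation"):
    """Median kernel and 5-95 percentile band per relation category."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bands = aggregate_band(kt, group_by=group_by)
    for cat, band in bands.items():
        color = _COLORS.get(str(cat))
        ax.plot(kt.grid, band["median"], label=f"{cat} (n={band['n']})", color=color)
        ax.fill_between(kt.grid, band["lo"], band["hi"], alpha=0.25, color=color)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("influence")
    ax.legend(frameon=False)
    return ax


def _gauss_ellipse(ax, pts, color, levels=(0.5, 0.95)):
    from matplotlib.patches import Ellipse
    from scipy.stats import chi2

    mu = pts.mean(axis=0)
    cov = np.cov(pts.T)
    vals, vecs = np.linalg.eigh(cov)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    for lv in levels:
        s = chi2.ppf(lv, df=2)
        w, h = 2 * np.sqrt(s * vals[-1]), 2 * np.sqrt(s * vals[0])
        ax.add_patch(Ellipse(mu, w, h, angle=angle, fill=False,
                             edgecolor=color, alpha=0.6))


def plot_pca_scatter(kt: KernelTable, proj: PCAProjection, ax=None,
                     ellipses: bool = True):
    """Kernels in the 2-D uncentered-PCA space, coloured by relation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    rel = kt.meta["relation"].to_numpy()
    for cat in np.unique(rel):
        m = rel == cat
        pts = proj.coords[m]
        color = _COLORS.get(str(cat))
        ax.scatter(pts[:, 0], pts[:, 1], s=18, label=cat, color=color)
        if ellipses and m.sum() >= 3:
            _gauss_ellipse(ax, pts, color)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False)
    return ax
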