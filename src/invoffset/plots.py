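"""Diagnostic figures: diversity vs ancestry, RDA biplot, index map.

Matplotlib is an optional dependency; importing this module without it
installed raises a clear error at call time rather than at package import.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gea import RdaResult
from .offset import AdaptiveIndexRaster


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as e:     # pragma: no cover
        raise ImportError("plotting requires matplotlib (install the "
                          "'plot' extra)") from e
    return plt


def plot_diversity_vs_ancestry(div: pd.DataFrame, qw: pd.Series,
                               status: pd.Series, metric: str = "He", ax=None):
    """Scatter of a diversity metric against ancestry with a quadratic fit."""
    plt = _plt()
    ax = ax or plt.gca()
    q = pd.Series(qw).reindex(div.index)
    for st, marker in (("native", "o"), ("introduced", "^"), ("farmed", "s")):
        sel = pd.Series(status).reindex(div.index) == st
        ax.scatter(q[sel], div.loc[sel, metric], marker=marker, label=st,
                   alpha=0.7)
    coef = np.polyfit(q, div[metric], 2)
    xs = np.linspace(0, 1, 100)
    ax.plot(xs, np.polyval(coef, xs), color="goldenrod")
    ax.set_xlabel("ancestry proportion (western cluster)")
    ax.set_ylabel(metric)
    ax.legend()
    return ax


def plot_rda_biplot(r: RdaResult, ax=None, arrow_scale: float = 1.0):
    """Sites, loci and environmental-variable arrows on the first two axes."""
    plt = _plt()
    ax = ax or plt.gca()
    axes = list(r.loadings.columns[:2])
    if len(axes) < 2:
        raise ValueError("biplot needs at least two constrained axes")
    ax.scatter(r.loadings[axes[0]], r.loadings[axes[1]], s=4,
               facecolors="none", edgecolors="grey", label="loci")
    site = r.site_scores[axes] / np.abs(r.site_scores[axes]).max()
    ax.scatter(site[axes[0]], site[axes[1]], s=40, color="dimgray",
               label="sites")
    for var in r.env_scores.index:
        x, y = r.env_scores.loc[var, axes[0]], r.env_scores.loc[var, axes[1]]
        ax.annotate(var, (x * arrow_scale, y * arrow_scale), color="navy")
        ax.arrow(0, 0, x * arrow_scale, y * arrow_scale, color="navy",
                 head_width=0.02, length_includes_head=True)
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    ax.set_xlabel(axes[0])
    ax.set_ylabel(axes[1])
    return ax


def plot_index_map(idx: AdaptiveIndexRaster, ax=None):
    """Genotype-environment index raster with a diverging colour scale."""
    plt = _plt()
    ax = ax or plt.gca()
    nrows, ncols = idx.grid.shape
    extent = (idx.xll, idx.xll + ncols * idx.cellsize,
              idx.yll, idx.yll + nrows * idx.cellsize)
    vmax = np.nanmax(np.abs(idx.grid))
    im = ax.imshow(idx.grid, extent=extent, cmap="RdBu_r", vmin=-vmax,
                   vmax=vmax)
    plt.colorbar(im, ax=ax, label=f"index ({idx.axis})")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax
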