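"""Minimal figures: metric scatter "maps" and dose-response panels."""

from __future__ import annotations

import numpy as np


def plot_metric_map(sites, metric: str, ax=None, min_richness: int = 5):
    """Scatter of per-site metric values colored by value (no projection).

    Expects ``x``/``y`` (or ``lon``/``lat``) coordinate columns; sites with
    total richness below ``min_richness`` are dropped, matching the analysis
    exclusion rule.
    """
    import matplotlib.pyplot as plt

    xcol = "x" if "x" in sites.columns else "lon"
    ycol = "y" if "y" in sites.columns else "lat"
    if xcol not in sites.columns or ycol not in sites.columns:
        raise ValueError("sites need x/y or lon/lat columns to map")
    if "total_richness" in sites.columns:
        sites = sites[sites["total_richness"] >= min_richness]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    sc = ax.scatter(sites[xcol], sites[ycol], c=sites[metric], s=8, cmap="viridis")
    ax.figure.colorbar(sc, ax=ax, label=metric)
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    ax.set_title(metric)
    return ax


def plot_dose_response(
    deposition, values, fit=None, band=None, anchors=None, ax=None, label=""
):
    """Metric vs deposition scatter with the fitted 90% quantile curve.

    ``band`` is an optional (grid, lower, upper) bootstrap envelope and
    ``anchors`` an optional sequence of (deposition, value) decline points.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(deposition, values, s=6, alpha=0.3, color="tab:green")
    if fit is not None:
        grid = np.linspace(np.min(deposition), np.max(deposition), 200)
        coefs = np.asarray(fit.coef)
        ax.plot(grid, np.polyval(coefs[::-1], grid), color="tab:blue", lw=2,
                label="90% quantile fit")
    if band is not None:
        grid, lo, hi = band
        ax.plot(grid, lo, color="black", lw=0.8)
        ax.plot(grid, hi, color="black", lw=0.8)
    if anchors is not None:
        xs, ys = zip(*anchors)
        ax.scatter(xs, ys, color="red", zorder=5, label="decline anchors")
    ax.set_xlabel("deposition (kg ha$^{-1}$ yr$^{-1}$)")
    ax.set_ylabel(label or "metric")
    if fit is not None or anchors is not None:
        ax.legend(frameon=False)
    return ax
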