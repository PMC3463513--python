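"""Presentation-only plotting helpers (never load-bearing for the analysis)."""

from __future__ import annotations

import numpy as np


def plot_rates_vs_rsa(rates, fits=None, groups=None, path=None, analysis="dnds"):
    """Per-bin rate estimates versus RSA with optional fitted lines.

    `rates` is the pipeline's rates table; `fits` the fits table. Returns
    the matplotlib figure; saves to `path` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    secol = f"se_{analysis}"
    for gname, sub in rates.groupby("group"):
        if groups is not None and gname not in groups:
            continue
        sub = sub.dropna(subset=[analysis])
        ax.errorbar(sub["x"], sub[analysis], yerr=sub[secol], fmt="o", label=gname, ms=4)
        if fits is not None:
            hit = fits[(fits.group == gname) & (fits.analysis == analysis)]
            if not hit.empty:
                r = hit.iloc[0]
                xs = np.linspace(0, 100, 50)
                ax.plot(xs, r.intercept + r.slope * xs, "-", lw=1)
    ax.set_xlabel("RSA (%)")
    ax.set_ylabel(analysis)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_fold_change(curve, fit=None, path=None, ylabel="fold change"):
    """Fold-change-versus-RSA curve with its weighted line fit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(curve["x"], curve["ratio"], yerr=curve["sigma"], fmt="o", ms=4)
    if fit is not None:
        xs = np.linspace(0, 100, 50)
        ax.plot(xs, fit.intercept + fit.slope * xs, "-", lw=1)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("RSA (%)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
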