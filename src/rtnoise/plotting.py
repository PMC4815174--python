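"""Plotting helpers: fitted-density overlays and recovery scatter panels."""

from __future__ import annotations

import numpy as np

from .exgauss import ExGaussParams, exgauss_pdf
from .recovery import RecoveryStudy

__all__ = ["plot_exgauss_fit", "plot_recovery_scatter"]


def plot_exgauss_fit(data, params: ExGaussParams, ax=None, bins: int = 30):
    """Histogram of an RT vector with the fitted ex-Gaussian density overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = np.asarray(data, dtype=float)
    ax.hist(data, bins=bins, density=True, color="lightgrey", edgecolor="grey")
    grid = np.linspace(data.min() - 50.0, data.max() + 50.0, 400)
    ax.plot(grid, exgauss_pdf(grid, params), color="black", lw=2)
    ax.set_xlabel("reaction time (ms)")
    ax.set_ylabel("density (1/ms)")
    return ax


def plot_recovery_scatter(study: RecoveryStudy, axes=None):
    """Noisy-fit vs clean-fit scatter per parameter, with identity and OLS lines."""
    import matplotlib.pyplot as plt

    names = study.param_names
    if axes is None:
        _, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 4))
    for ax, name in zip(np.atleast_1d(axes), names):
        usable = [r for r in study.records if r.usable]
        x = np.array([r.clean[name] for r in usable])
        y = np.array([r.noisy[name] for r in usable])
        reg = study.regress(name)
        ax.scatter(x, y, s=8, alpha=0.5, color="grey")
        lims = np.array([min(x.min(), y.min()), max(x.max(), y.max())])
        ax.plot(lims, lims, color="black", lw=1, label="identity")
        ax.plot(lims, reg.intercept + reg.slope * lims, color="crimson", lw=1.5, label="OLS")
        ax.set_title(name)
        ax.set_xlabel("clean fit")
        ax.set_ylabel("noisy fit")
        ax.legend(frameon=False, fontsize=8)
    return axes
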