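"""Convenience figures: QQ, scale-location, grid and forest plots.

Figures are a presentation layer over the TSV/JSON outputs; all numbers they
show are produced by the library functions, never recomputed here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402


def plot_qq(diag, ax=None):
    """Normal quantile-quantile plot of studentized residuals."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(diag.qq_theoretical, diag.qq_sample, s=6, alpha=0.5)
    lim = [diag.qq_theoretical.min(), diag.qq_theoretical.max()]
    ax.plot(lim, lim, color="red", lw=1)
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("studentized residuals")
    ax.set_title("Normal Q-Q")
    return ax


def plot_scale_location(diag, ax=None):
    """Scale-location plot: sqrt(|studentized residual|) against fitted."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(diag.fitted, diag.sqrt_abs_std_residuals, s=6, alpha=0.5)
    ax.axhline(float(diag.sqrt_abs_std_residuals.mean()), color="red", lw=1)
    ax.set_xlabel("fitted values")
    ax.set_ylabel(r"$\sqrt{|\mathrm{std.\ residual}|}$")
    ax.set_title("Scale-location")
    return ax


def plot_grid(grid_df, ax=None):
    """Back-calculated true hazard ratio against the confounder odds ratio."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(grid_df["beta_ux"], grid_df["true_hr"], marker="o")
    ax.axhline(1.0, color="grey", lw=1, ls="--")
    ax.set_xlabel(r"confounder effect $\beta_{UX}$ (log odds ratio)")
    ax.set_ylabel("true hazard ratio")
    return ax


def plot_forest(labels, hrs, ci_lows, ci_highs, ax=None):
    """Forest plot of hazard ratios with 95% CIs."""
    if ax is None:
        _, ax = plt.subplots()
    y = range(len(labels))
    for yi, hr, lo, hi in zip(y, hrs, ci_lows, ci_highs):
        ax.plot([lo, hi], [yi, yi], color="black", lw=1)
        ax.plot(hr, yi, "s", color="black")
    ax.axvline(1.0, color="grey", lw=1, ls="--")
    ax.set_yticks(list(y))
    ax.set_yticklabels(labels)
    ax.set_xlabel("hazard ratio")
    return ax
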