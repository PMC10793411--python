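"""Plots of ensemble population statistics and proxy comparisons."""

from __future__ import annotations

import numpy as np

from .population import EnsembleStats

__all__ = ["plot_population_stats", "plot_comparison"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_population_stats(stats: EnsembleStats, statistic: str = "cv2", ax=None, **kwargs):
    """⟨N(t)⟩ or CV²_N(t) with the 95% bootstrap band, if available."""
    ax = _get_ax(ax)
    if statistic == "mean":
        y, lo, hi, label = stats.mean_N, stats.ci_mean_low, stats.ci_mean_high, r"$\langle N \rangle$"
        ax.set_yscale("log")
    elif statistic == "cv2":
        y, lo, hi, label = stats.cv2_N, stats.ci_cv2_low, stats.ci_cv2_high, r"$CV_N^2$"
    else:
        raise ValueError("statistic must be 'mean' or 'cv2'")
    (line,) = ax.plot(stats.time_grid, y, **kwargs)
    if lo is not None:
        ax.fill_between(stats.time_grid, lo, hi, alpha=0.25, color=line.get_color(), lw=0)
    ax.set_xlabel("time")
    ax.set_ylabel(label)
    return ax


def plot_comparison(result, path=None):
    """Observed vs per-proxy simulated ⟨N⟩ and CV²_N; optionally saved."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    obs = result.observed
    keep = np.isin(obs.time_grid, result.grid)
    ax1.errorbar(
        obs.time_grid[keep],
        obs.mean_N[keep],
        yerr=None if obs.ci_mean_low is None else (
            obs.mean_N[keep] - obs.ci_mean_low[keep],
            obs.ci_mean_high[keep] - obs.mean_N[keep],
        ),
        fmt="k.",
        label="observed",
    )
    ax2.errorbar(
        obs.time_grid[keep],
        obs.cv2_N[keep],
        yerr=None if obs.ci_cv2_low is None else (
            obs.cv2_N[keep] - obs.ci_cv2_low[keep],
            obs.ci_cv2_high[keep] - obs.cv2_N[keep],
        ),
        fmt="k.",
        label="observed",
    )
    for proxy, stats in result.simulated.items():
        ax1.plot(stats.time_grid, stats.mean_N, label=proxy)
        ax2.plot(stats.time_grid, stats.cv2_N, label=proxy)
    ax1.set_yscale("log")
    ax1.set_ylabel(r"$\langle N \rangle$")
    ax2.set_ylabel(r"$CV_N^2$")
    ax2.set_xlabel("time (min)")
    ax1.legend(frameon=False, fontsize=8)
    fig.suptitle(f"best proxy: {result.best_proxy}")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
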