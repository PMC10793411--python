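"""Synchronised ensemble statistics of colony population numbers.

Colonies are synchronised at progenitor birth (t = 0, N = 1).  On a common
time grid the ensemble mean ⟨N⟩, variance σ²_N and squared coefficient of
variation CV²_N = σ²_N/⟨N⟩² are computed, with percentile-bootstrap
confidence intervals resampling whole colonies (the exchangeable unit).

Closed-form oracles for the exponential timer (a Yule process) are included:
N(t) is geometric with mean e^{μt}, so CV²_N(t) = 1 − e^{−μt}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import ColonyEvents, biomass_trace

__all__ = [
    "EnsembleStats",
    "population_moments",
    "yule_cv2",
    "geometric_pmf",
    "bootstrap_ci",
    "biomass_decomposition",
    "default_grid",
]


@dataclass
class EnsembleStats:
    """Per-time-point moments of N across colonies, with 95% bootstrap CIs."""

    time_grid: np.ndarray
    mean_N: np.ndarray
    var_N: np.ndarray
    cv2_N: np.ndarray
    n_colonies: int
    ci_mean_low: np.ndarray | None = None
    ci_mean_high: np.ndarray | None = None
    ci_cv2_low: np.ndarray | None = None
    ci_cv2_high: np.ndarray | None = None

    def to_frame(self):
        """Tidy DataFrame: one row per (time, statistic)."""
        import pandas as pd

        rows = []
        for name, val, lo, hi in (
            ("mean_N", self.mean_N, self.ci_mean_low, self.ci_mean_high),
            ("cv2_N", self.cv2_N, self.ci_cv2_low, self.ci_cv2_high),
        ):
            for j, t in enumerate(self.time_grid):
                rows.append(
                    {
                        "time": t,
                        "statistic": name,
                        "value": val[j],
                        "ci_low": np.nan if lo is None else lo[j],
                        "ci_high": np.nan if hi is None else hi[j],
                    }
                )
        return pd.DataFrame(rows)


def default_grid(t_max: float, n_points: int = 64) -> np.ndarray:
    """Uniform evaluation grid over [0, t_max]."""
    return np.linspace(0.0, float(t_max), n_points)


def _counts_matrix(colonies, grid: np.ndarray) -> np.ndarray:
    if isinstance(colonies, np.ndarray) and colonies.ndim == 2:
        return colonies
    first = colonies[0]
    if isinstance(first, ColonyEvents):
        return np.stack([c.n_at(grid) for c in colonies])
    return np.stack([np.asarray(c, dtype=float) for c in colonies])


def _moments(N: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = N.mean(axis=0)
    var = N.var(axis=0, ddof=1)
    cv2 = np.where(mean > 0, var / mean**2, 0.0)
    return mean, var, cv2


def population_moments(
    colonies,
    grid: Sequence[float],
    n_boot: int = 0,
    seed=None,
    level: float = 0.95,
) -> EnsembleStats:
    """Ensemble moments of N(t) on a grid, optionally with bootstrap CIs.

    ``colonies`` may be a list of :class:`ColonyEvents`, a list of per-grid
    N vectors, or an (n_colonies, n_grid) count matrix (N evaluated
    right-continuously: a division at t counts at t).  With ``n_boot > 0``,
    95% percentile-bootstrap intervals are attached, resampling colonies so
    within-colony time correlation is preserved.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be a 1-D non-decreasing array")
    N = _counts_matrix(colonies, grid)
    if N.shape[0] < 2:
        raise ValueError("need at least 2 colonies for ensemble moments")
    mean, var, cv2 = _moments(N)
    stats = EnsembleStats(
        time_grid=grid, mean_N=mean, var_N=var, cv2_N=cv2, n_colonies=N.shape[0]
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = N.shape[0]
        boot_mean = np.empty((n_boot, grid.size))
        boot_cv2 = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            m, _, c = _moments(N[idx])
            boot_mean[b], boot_cv2[b] = m, c
        alpha = (1.0 - level) / 2.0
        stats.ci_mean_low, stats.ci_mean_high = np.quantile(
            boot_mean, [alpha, 1 - alpha], axis=0
        )
        stats.ci_cv2_low, stats.ci_cv2_high = np.quantile(
            boot_cv2, [alpha, 1 - alpha], axis=0
        )
    return stats


def yule_cv2(t, mu: float):
    """CV²_N(t) = 1 − e^{−μt} of the exponential timer (Yule process)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = 1.0 - np.exp(-mu * t)
    return float(out) if out.ndim == 0 else out


def geometric_pmf(n, t: float, mu: float):
    """P(N(t) = n) for the exponential timer: geometric with mean e^{μt}.

    P(N = n) = p(1 − p)^{n−1} with success probability p = e^{−μt}.
    """
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    p = np.exp(-mu * t)
    out = p * (1.0 - p) ** (n - 1)
    return float(out) if out.ndim == 0 else out


def bootstrap_ci(
    per_colony_values: Sequence[float],
    statistic: str = "mean",
    n_boot: int = 1000,
    seed=None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a per-colony statistic.

    ``statistic`` is ``"mean"`` or ``"cv2"`` (plug-in variance/mean² with
    unbiased variance).  All-equal input yields a zero-width interval.
    """
    x = np.asarray(per_colony_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if statistic == "mean":
        stat = lambda v: v.mean(axis=-1)
    elif statistic == "cv2":
        stat = lambda v: v.var(axis=-1, ddof=1) / v.mean(axis=-1) ** 2
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    vals = stat(x[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def local_maxima(values: Sequence[float], smooth: int = 3) -> np.ndarray:
    """Indices of strict local maxima after a moving-average smooth.

    Used to detect the damped oscillations of CV²_N(t) on a Monte-Carlo
    grid; the default 3-point smooth suppresses single-point jitter.
    """
    y = np.asarray(values, dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        y = np.convolve(y, kernel, mode="valid")
        offset = (smooth - 1) // 2
    else:
        offset = 0
    idx = np.where((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1
    return idx + offset


def biomass_decomposition(
    colonies: Sequence[ColonyEvents], grid: Sequence[float]
) -> "pd.DataFrame":
    """Both sides of the population-noise decomposition, per grid point.

    For size-coupled (adder-family) colonies the population noise satisfies

        CV²_N ≈ CV²_B + CV²_s / ⟨N⟩,

    where B is total colony biomass and CV²_s the within-colony cell-size
    noise (averaged across colonies).  Returns a DataFrame with columns
    ``time, cv2_N, cv2_B, mean_cv2_s, mean_N, rhs`` for diagnostic
    comparison; the approximation is asymptotic in ⟨N⟩ and is reported, not
    asserted, at small N.
    """
    import pandas as pd

    grid = np.asarray(grid, dtype=float)
    if not colonies or not colonies[0].config.is_adder_family:
        raise ValueError("biomass decomposition requires adder-family colonies with sizes")
    mu = colonies[0].config.growth_rate_mu
    N = np.stack([c.n_at(grid) for c in colonies])
    B = np.stack([biomass_trace(c, grid).biomass for c in colonies])
    # within-colony size CV² per time: sizes of live cells
    cv2_s = np.zeros((len(colonies), grid.size))
    for i, c in enumerate(colonies):
        births = np.array([a.birth_time for a in c.agents])
        divs = np.array([a.division_time for a in c.agents])
        sbs = np.array([a.birth_size_sb for a in c.agents])
        for j, t in enumerate(grid):
            alive = (births <= t) & (divs > t)
            s = sbs[alive] * np.exp(mu * (t - births[alive]))
            if s.size > 1:
                cv2_s[i, j] = s.var() / s.mean() ** 2
    mean_N, _, cv2_N = _moments(N)
    mean_B, _, cv2_B = _moments(B)
    mean_cv2_s = cv2_s.mean(axis=0)
    return pd.DataFrame(
        {
            "time": grid,
            "cv2_N": cv2_N,
            "cv2_B": cv2_B,
            "mean_cv2_s": mean_cv2_s,
            "mean_N": mean_N,
            "rhs": cv2_B + mean_cv2_s / mean_N,
        }
    )
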