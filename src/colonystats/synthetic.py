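"""Synthetic microfluidic lineage tables with known ground truth.

Emulates the tabular output of segmentation-and-tracking software for
time-lapse colonies of a rod-shaped bacterium growing in open cultivation
chambers: one row per cell per frame with colony id, cell id, parent id,
time (minutes), cell length (µm) and projected area (µm²).

Each colony starts from a single newborn progenitor at t = 0 and follows
an adder on a chosen governing size proxy (length, surface area, or
volume): the progenitor size is gamma(mean_sb, cv2_sb), added sizes are
gamma(mean_delta_d, cv2_delta_d), growth is exponential at a shared rate
μ, and division is exact symmetric halving in the governing proxy.  Each
cell draws one width per cycle (gamma, independent across cells); the
proxy size is converted to (length, projected area) through the capsule
geometry, frames are sampled every ``frame_interval`` minutes, and
multiplicative lognormal measurement noise (default 3% cv) is applied to
length and projected area independently.

Defaults mirror the measured growth conditions of *C. glutamicum* in
microfluidic chambers: surface area as the governing proxy with
mean Δd = 4.75 µm² (CV² = 0.058), progenitor mean 5.69 µm² (CV² = 0.025),
doubling time 75.2 min, 10-min frames, 154 colonies, 6 generations, and
~10% cell-to-cell width variability around 0.96 µm (the width noise
implied by the newborn length and area noise when length and width vary
independently).

A ground-truth annex (one row per cell: true width, true birth/division
sizes and times, drawn Δd) accompanies every table so downstream
estimators can be validated exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import LINEAGE_COLUMNS, PROGENITOR_PARENT
from .simulate import StrategyConfig, simulate_counts

__all__ = ["GeneratorParams", "LineageTable", "generate_dataset", "generate_population_counts"]

_PROXY_NAMES = ("length", "area", "volume")


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions of the synthetic time-lapse experiment."""

    governing_proxy: str = "area"
    doubling_time_min: float = 75.2
    mean_delta_d: float = 4.75
    cv2_delta_d: float = 0.058
    mean_sb: float = 5.69
    cv2_sb: float = 0.025
    mean_w: float = 0.96
    cv2_w: float = 0.010
    cv_meas: float = 0.03
    frame_interval: float = 10.0
    n_colonies: int = 154
    max_generations: int = 6
    seed: int = 0
    #: optional within-cycle width-noise profile: relative slope of CV_w²
    #: across the cycle (negative = noise shrinks as the cycle progresses);
    #: None keeps the default one-gamma-width-per-cycle model
    width_noise_slope: float | None = None

    def __post_init__(self):
        if self.governing_proxy not in _PROXY_NAMES:
            raise ValueError(f"governing_proxy must be one of {_PROXY_NAMES}")
        for name in ("doubling_time_min", "mean_delta_d", "mean_sb", "mean_w", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cv2_delta_d", "cv2_sb", "cv2_w", "cv_meas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_colonies < 1 or self.max_generations < 1:
            raise ValueError("n_colonies and max_generations must be >= 1")

    @property
    def growth_rate_mu(self) -> float:
        """Per-minute exponential growth rate, ln 2 / doubling time."""
        return math.log(2.0) / self.doubling_time_min

    def strategy_config(self) -> StrategyConfig:
        return StrategyConfig(
            strategy="adder",
            growth_rate_mu=self.growth_rate_mu,
            mean_delta_d=self.mean_delta_d,
            cv2_delta_d=self.cv2_delta_d,
            mean_sb=self.mean_sb,
            cv2_sb=self.cv2_sb,
        )


@dataclass
class LineageTable:
    """Frame-level table plus per-cell ground truth and the generator params."""

    frames: pd.DataFrame
    ground_truth: pd.DataFrame
    params: GeneratorParams
    n_redrawn_colonies: int = 0

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)

    def write(self, csv_path, truth_path=None) -> None:
        """Write the table CSV and a ground-truth JSON sidecar."""
        self.to_csv(csv_path)
        if truth_path is None:
            truth_path = Path(csv_path).with_suffix(".truth.json")
        payload = {
            "params": asdict(self.params),
            "n_redrawn_colonies": self.n_redrawn_colonies,
            "cells": self.ground_truth.to_dict(orient="list"),
        }
        Path(truth_path).write_text(json.dumps(payload))

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        df = pd.read_csv(path)
        missing = [c for c in LINEAGE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return df


def _gamma(rng, mean, cv2, size=None):
    if cv2 == 0:
        return mean if size is None else np.full(size, mean)
    return rng.gamma(1.0 / cv2, mean * cv2, size=size)


def _lognoise(rng, cv, size):
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def _length_from_proxy(proxy: str, s: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Tip-to-tip length of a capsule whose governing-proxy size is s."""
    if proxy == "length":
        return s
    if proxy == "area":
        return s / (np.pi * w)
    # volume: V = πLw²/4 − πw³/12 is linear in L
    return (s + np.pi * w**3 / 12.0) / (np.pi * w**2 / 4.0)


def _simulate_colony_tree(params: GeneratorParams, rng) -> list[dict]:
    """Cells of one colony: adder on the governing proxy, by generation."""
    mu = params.growth_rate_mu
    cells = []
    sb0 = float(_gamma(rng, params.mean_sb, params.cv2_sb))
    frontier = [dict(cell_id=0, parent_id=PROGENITOR_PARENT, generation=0, birth_time=0.0, sb=sb0)]
    next_id = 1
    while frontier:
        new = []
        for c in frontier:
            if c["generation"] < params.max_generations:
                delta = float(_gamma(rng, params.mean_delta_d, params.cv2_delta_d))
                sd = c["sb"] + delta
                tau = math.log(sd / c["sb"]) / mu
                c.update(delta_d=delta, sd=sd, division_time=c["birth_time"] + tau)
                for _ in range(2):
                    new.append(
                        dict(
                            cell_id=next_id,
                            parent_id=c["cell_id"],
                            generation=c["generation"] + 1,
                            birth_time=c["division_time"],
                            sb=sd / 2.0,
                        )
                    )
                    next_id += 1
            else:
                c.update(delta_d=np.nan, sd=np.nan, division_time=np.nan)
            cells.append(c)
        frontier = new
    return cells


def generate_dataset(params: GeneratorParams) -> LineageTable:
    """Generate a lineage table with ground truth for the given conditions.

    Colonies whose geometry is inconsistent (a cell with inferred length
    below its width at birth, or a cell living shorter than one frame so
    that its parent link would dangle) are redrawn with fresh randomness;
    more than 1% redraws across the run raises, since that signals
    parameters outside the capsule regime rather than bad luck.
    """
    master = np.random.SeedSequence(params.seed)
    frame_rows = []
    truth_rows = []
    n_redrawn = 0
    max_redraws = max(10, params.n_colonies // 10)
    colony = 0
    streams = iter(master.spawn(params.n_colonies + max_redraws))
    while colony < params.n_colonies:
        rng = np.random.default_rng(next(streams))
        cells = _simulate_colony_tree(params, rng)

        # movie ends one frame after the last division of the tracked tree
        divs = [c["division_time"] for c in cells if np.isfinite(c["division_time"])]
        t_end = max(divs) if divs else params.frame_interval
        movie_end = math.ceil(t_end / params.frame_interval) * params.frame_interval

        ok = True
        widths = {}
        for c in cells:
            # width draw subject to geometric feasibility: the cell's birth
            # size must admit a capsule with L >= w (stubby newborns truncate
            # the upper width tail, as for a real rod that cannot be wider
            # than its size allows)
            w = None
            for _ in range(100):
                cand = float(_gamma(rng, params.mean_w, params.cv2_w))
                L_b = _length_from_proxy(
                    params.governing_proxy, np.array([c["sb"]]), np.array([cand])
                )[0]
                if L_b >= cand:
                    w = cand
                    break
            if w is None:
                ok = False
                break
            widths[c["cell_id"]] = w
            end = c["division_time"] if np.isfinite(c["division_time"]) else movie_end + 1e-9
            first = math.ceil(c["birth_time"] / params.frame_interval - 1e-12) * params.frame_interval
            if first >= end and np.isfinite(c["division_time"]):
                ok = False  # cell never imaged: its children's parent would dangle
                break
        if not ok:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    f"more than {max_redraws} colony redraws: parameters are "
                    "geometrically inconsistent with a capsule"
                )
            continue

        mu = params.growth_rate_mu
        for c in cells:
            w = widths[c["cell_id"]]
            end = c["division_time"] if np.isfinite(c["division_time"]) else movie_end + 1e-9
            first = math.ceil(c["birth_time"] / params.frame_interval - 1e-12) * params.frame_interval
            times = np.arange(first, min(end, movie_end + 1e-9), params.frame_interval)
            # a frame exactly at the division instant belongs to the daughters
            times = times[times < end - 1e-12]
            if times.size == 0:
                continue  # leaf born in the movie's final sliver
            s = c["sb"] * np.exp(mu * (times - c["birth_time"]))
            if params.width_noise_slope is None:
                w_t = np.full(times.size, w)
            else:
                # width noise profile: per-cell standard normal score, CV_w²
                # scaled linearly across the cycle phase
                tau = (
                    c["division_time"] - c["birth_time"]
                    if np.isfinite(c["division_time"])
                    else math.log(1.0 + params.mean_delta_d / c["sb"]) / mu
                )
                phase = np.clip((times - c["birth_time"]) / tau, 0.0, 1.0)
                scale = np.clip(1.0 + params.width_noise_slope * (phase - 0.5), 0.05, None)
                z = rng.standard_normal()
                sig2 = np.log1p(params.cv2_w * scale)
                w_t = params.mean_w * np.exp(z * np.sqrt(sig2) - 0.5 * sig2)
            L = _length_from_proxy(params.governing_proxy, s, w_t)
            Ap = w_t * (L - w_t) + np.pi * (w_t / 2.0) ** 2
            L_obs = L * _lognoise(rng, params.cv_meas, L.size)
            Ap_obs = Ap * _lognoise(rng, params.cv_meas, Ap.size)
            for t, lo, ao in zip(times, L_obs, Ap_obs):
                frame_rows.append((colony, c["cell_id"], c["parent_id"], t, lo, ao))
            truth_rows.append(
                dict(
                    colony_id=colony,
                    cell_id=c["cell_id"],
                    parent_id=c["parent_id"],
                    generation=c["generation"],
                    birth_time=c["birth_time"],
                    division_time=c["division_time"],
                    sb_true=c["sb"],
                    sd_true=c["sd"],
                    delta_d_true=c["delta_d"],
                    width_true=w,
                )
            )
        colony += 1

    frames = pd.DataFrame(frame_rows, columns=LINEAGE_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return LineageTable(frames=frames, ground_truth=truth, params=params, n_redrawn_colonies=n_redrawn)


def generate_population_counts(
    params: GeneratorParams, t_max: float, grid=None, n_colonies: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-colony N(t) trajectories (counting only, no geometry).

    Returns ``(grid, counts)`` with ``counts`` of shape (n_colonies,
    len(grid)); colonies are synchronised at progenitor birth, as the
    experimental counting produces.
    """
    if grid is None:
        grid = np.arange(0.0, t_max + 1e-9, params.frame_interval)
    grid = np.asarray(grid, dtype=float)
    n = params.n_colonies if n_colonies is None else n_colonies
    counts = simulate_counts(params.strategy_config(), n, grid, params.seed, t_max=t_max)
    return grid, counts
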