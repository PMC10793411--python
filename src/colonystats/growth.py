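"""Per-cell-cycle growth reconstruction and size-regulation statistics.

Input is a frame-level lineage table (one row per cell per frame) with
columns ``colony_id, cell_id, parent_id, time_min, length_um,
projected_area_um2``; ``parent_id = -1`` marks colony progenitors.  From it
the module

* infers capsule width per frame and derives surface area and volume
  (:func:`annotate_shapes`),
* reconstructs cell cycles and fits exponential growth ``s(t) = s_b e^{μt}``
  per cycle and per size proxy by OLS on log size, extrapolating the fit to
  the birth and division instants (:func:`reconstruct_cycles`),
* summarises newborn and added sizes per proxy (means, squared CVs, the
  adder correlation R between Δd and s_b) with percentile-bootstrap CIs
  (:func:`newborn_and_added_size_summary`),
* measures lineage correlations and cycle-phase-resolved dimension noise.

Cycle boundaries
----------------
A cell is born when it first appears; it divides when its daughters first
appear.  Frames are Δt apart, so either event is only localised to within
one frame interval.  Two conventions are supported: ``"midpoint"``
(default) places the boundary half an interval before the first frame of
the newborn(s), which makes the extrapolated sizes unbiased to first order
in μΔt; ``"frame"`` uses the frame of appearance itself (sizes then carry
a systematic e^{μδ} factor, δ ∈ [0, Δt)).

Measurement-error correction
----------------------------
Extrapolated s_b and s_d carry estimation noise (propagated OLS error of
the log-linear fit) plus boundary-localisation jitter (multiplicative
variance (μΔt)²/12 per boundary under a uniform offset).  Both inflate the
observed variance of s_b and Δd and bias the Δd–s_b correlation downward.
The summary subtracts the mean estimated measurement variance from the
across-cycle variances and covariance (a moment-based errors-in-variables
correction); raw plug-in values are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LINEAGE_COLUMNS",
    "PROXIES",
    "CycleFitError",
    "GrowthFit",
    "CellCycleRecord",
    "ProxySummary",
    "SizeRegulationSummary",
    "CorrelationResult",
    "fit_exponential_growth",
    "annotate_shapes",
    "reconstruct_cycles",
    "newborn_and_added_size_summary",
    "division_strategy_correlation",
    "lineage_correlations",
    "cycle_phase_noise",
]

LINEAGE_COLUMNS = [
    "colony_id",
    "cell_id",
    "parent_id",
    "time_min",
    "length_um",
    "projected_area_um2",
]

#: size proxies and the frame columns that carry them after annotate_shapes
PROXIES = {
    "length": "length_um",
    "area": "surface_area_um2",
    "volume": "volume_um3",
}

PROGENITOR_PARENT = -1


class CycleFitError(ValueError):
    """A cell cycle cannot be fitted; carries a machine-readable reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class GrowthFit:
    """Exponential fit of one cycle: s(t) = s_b e^{μ(t − t_birth)}.

    ``var_log_sb``/``var_log_sd``/``cov_log`` are the OLS variances and
    covariance of the fitted log size at the birth and division instants.
    """

    mu: float
    sb: float
    sd: float
    n_frames: int
    var_log_sb: float
    var_log_sd: float
    cov_log: float

    def __iter__(self):  # allows mu, sb, sd = fit_exponential_growth(...)
        return iter((self.mu, self.sb, self.sd))


@dataclass(frozen=True)
class CellCycleRecord:
    """One reconstructed cycle for one size proxy."""

    colony_id: int
    cell_id: int
    parent_id: int
    proxy: str
    birth_time: float
    division_time: float | None
    mu: float
    sb_extrapolated: float
    sd_extrapolated: float | None
    delta_d: float | None
    tau_d: float | None
    n_frames: int


def _ols_log(times: np.ndarray, sizes: np.ndarray, t_birth: float, t_div: float) -> GrowthFit:
    n = times.size
    x, y = times.astype(float), np.log(sizes.astype(float))
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0:
        raise CycleFitError("zero_time_span")
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2) / (n - 2)) if n > 2 else 0.0

    def v_at(t0):
        return s2 * (1.0 / n + (t0 - xbar) ** 2 / sxx)

    cov = s2 * (1.0 / n + (t_birth - xbar) * (t_div - xbar) / sxx)
    return GrowthFit(
        mu=slope,
        sb=float(np.exp(intercept + slope * t_birth)),
        sd=float(np.exp(intercept + slope * t_div)),
        n_frames=n,
        var_log_sb=v_at(t_birth),
        var_log_sd=v_at(t_div),
        cov_log=cov,
    )


def fit_exponential_growth(
    series: Sequence[tuple[float, float]] | pd.DataFrame,
    birth_time: float,
    division_time: float,
) -> GrowthFit:
    """OLS fit of log size against time; extrapolates to the cycle boundaries.

    ``series`` is a sequence of (time, size) pairs (or a two-column
    DataFrame).  Requires at least 3 strictly positive sizes and a nonzero
    time span; violations raise :class:`CycleFitError` with reason codes
    ``"too_few_frames"``, ``"nonpositive_size"`` or ``"zero_time_span"``.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (time, size) pairs")
    t, s = arr[:, 0], arr[:, 1]
    if np.any(s <= 0):
        raise CycleFitError("nonpositive_size")
    if t.size < 3:
        raise CycleFitError("too_few_frames", f"got {t.size}")
    if division_time <= birth_time:
        raise CycleFitError("zero_time_span", "division_time <= birth_time")
    return _ols_log(t, s, birth_time, division_time)


# ---------------------------------------------------------------------------
# table-level operations


def validate_lineage_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema check; violations are reported with the offending row numbers."""
    missing = [c for c in LINEAGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"lineage table is missing columns {missing}")
    if len(table) == 0:
        raise ValueError("lineage table is empty")
    bad = ~np.isfinite(
        table[["time_min", "length_um", "projected_area_um2"]].to_numpy(float)
    ).all(axis=1)
    if bad.any():
        rows = list(table.index[bad][:10])
        raise ValueError(
            f"{int(bad.sum())} rows with non-finite measurements (first rows: {rows})"
        )
    return table


def annotate_shapes(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Add capsule width, surface area and volume columns to a lineage table.

    The width inversion is vectorised; frames whose (A_p, L) admit no
    capsule width in (0, L] are dropped.  Returns the annotated table and
    the number of dropped frames.
    """
    validate_lineage_table(table)
    L = table["length_um"].to_numpy(dtype=float)
    Ap = table["projected_area_um2"].to_numpy(dtype=float)
    a = np.pi / 4.0 - 1.0
    pos = (L > 0) & (Ap > 0)
    disc = np.where(pos, L * L + 4.0 * a * Ap, np.nan)
    with np.errstate(invalid="ignore"):
        w = (-L + np.sqrt(disc)) / (2.0 * a)
    valid = pos & np.isfinite(w) & (w > 0) & (w <= L * (1 + 1e-9))
    w = np.minimum(w, L)
    out = table.loc[valid].copy()
    wv = w[valid]
    Lv = out["length_um"].to_numpy(dtype=float)
    out["width_um"] = wv
    out["surface_area_um2"] = np.pi * Lv * wv
    out["volume_um3"] = np.pi * Lv * wv**2 / 4.0 - np.pi * wv**3 / 12.0
    return out, int((~valid).sum())


def _grouped_ols(codes, n_groups, t, y, t0, t1):
    """Vectorised per-group OLS of y on t with extrapolation to t0/t1.

    Returns dict of per-group arrays: slope, log value and variance at t0
    and t1, and their covariance.  Groups with zero time spread get NaN.
    """
    n = np.bincount(codes, minlength=n_groups).astype(float)
    Sx = np.bincount(codes, t, minlength=n_groups)
    Sy = np.bincount(codes, y, minlength=n_groups)
    Sxx = np.bincount(codes, t * t, minlength=n_groups)
    Sxy = np.bincount(codes, t * y, minlength=n_groups)
    Syy = np.bincount(codes, y * y, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar, ybar = Sx / n, Sy / n
        sxx = Sxx - n * xbar**2
        sxy = Sxy - n * xbar * ybar
        syy = Syy - n * ybar**2
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        intercept = ybar - slope * xbar
        rss = np.maximum(syy - slope * sxy, 0.0)
        s2 = np.where(n > 2, rss / np.maximum(n - 2, 1), 0.0)
        y0 = intercept + slope * t0
        y1 = intercept + slope * t1
        v0 = s2 * (1.0 / n + (t0 - xbar) ** 2 / sxx)
        v1 = s2 * (1.0 / n + (t1 - xbar) ** 2 / sxx)
        cov = s2 * (1.0 / n + (t0 - xbar) * (t1 - xbar) / sxx)
    return {"n": n, "mu": slope, "y0": y0, "y1": y1, "v0": v0, "v1": v1, "cov": cov, "sxx": sxx}


def reconstruct_cycles(
    table: pd.DataFrame,
    boundary: str = "midpoint",
    min_frames: int = 3,
    frame_interval: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct cell cycles from a lineage table, fitting all three proxies.

    Returns ``(cycles, exclusions)``.  ``cycles`` has one row per
    (colony_id, cell_id, proxy) with the fitted μ, extrapolated s_b/s_d,
    Δd = s_d − s_b, τd, the log-space fit variances, and a ``censored``
    flag (no observed division).  ``exclusions`` lists every candidate cell
    dropped, with a reason code — counts always add up to the number of
    candidate cells (no silent drops).
    """
    if boundary not in ("midpoint", "frame"):
        raise ValueError("boundary must be 'midpoint' or 'frame'")
    frames, n_bad_shape = annotate_shapes(table)
    if frame_interval is None:
        dt = frames.sort_values("time_min").groupby(["colony_id", "cell_id"])["time_min"].diff()
        frame_interval = float(dt.dropna().median()) if dt.notna().any() else 0.0

    # candidate cells come from the *raw* table so excluded ones are counted
    raw_cells = table.groupby(["colony_id", "cell_id"], sort=True)
    raw_info = raw_cells.agg(
        parent_id=("parent_id", "first"),
        nonpos=("length_um", lambda v: bool((np.asarray(v) <= 0).any())),
    )
    nonpos_ap = raw_cells["projected_area_um2"].apply(lambda v: bool((np.asarray(v) <= 0).any()))
    raw_info["nonpos"] = raw_info["nonpos"] | nonpos_ap

    cells = frames.groupby(["colony_id", "cell_id"], sort=True).agg(
        parent_id=("parent_id", "first"),
        first_time=("time_min", "min"),
        last_time=("time_min", "max"),
        n_frames=("time_min", "size"),
    )
    # division event per mother: first appearance of any child
    child_first = (
        frames[frames["parent_id"] != PROGENITOR_PARENT]
        .groupby(["colony_id", "parent_id"])["time_min"]
        .min()
    )
    child_first.index = child_first.index.set_names(["colony_id", "cell_id"])
    cells = cells.join(child_first.rename("child_first"))

    half = frame_interval / 2.0 if boundary == "midpoint" else 0.0
    is_progenitor = cells["parent_id"] == PROGENITOR_PARENT
    cells["birth_time"] = np.where(
        is_progenitor, cells["first_time"], cells["first_time"] - half
    )
    cells["division_time"] = cells["child_first"] - half
    cells["censored"] = cells["child_first"].isna()

    # exclusions with precedence: nonpositive size, then too few frames
    excl_rows = []
    kept = []
    for key in raw_info.index:
        if raw_info.loc[key, "nonpos"]:
            excl_rows.append((*key, "nonpositive_size"))
        elif key not in cells.index or cells.loc[key, "n_frames"] < min_frames:
            excl_rows.append((*key, "too_few_frames"))
        else:
            kept.append(key)
    cells = cells.loc[kept]

    key_frame = pd.MultiIndex.from_frame(frames[["colony_id", "cell_id"]])
    in_kept = np.asarray(key_frame.isin(cells.index))
    frames = frames.loc[in_kept]
    key_frame = pd.MultiIndex.from_frame(frames[["colony_id", "cell_id"]])
    codes = cells.index.get_indexer(key_frame)
    n_groups = len(cells)

    t = frames["time_min"].to_numpy(dtype=float)
    t0 = cells["birth_time"].to_numpy(dtype=float)
    # censored cells: the fit is evaluated up to the last observed frame
    t1 = np.where(
        cells["censored"], cells["last_time"], cells["division_time"]
    ).astype(float)

    pieces = []
    for proxy, col in PROXIES.items():
        y = np.log(frames[col].to_numpy(dtype=float))
        g = _grouped_ols(codes, n_groups, t, y, t0, t1)
        df = pd.DataFrame(
            {
                "colony_id": cells.index.get_level_values(0),
                "cell_id": cells.index.get_level_values(1),
                "parent_id": cells["parent_id"].to_numpy(),
                "proxy": proxy,
                "birth_time": cells["birth_time"].to_numpy(float),
                "division_time": np.where(cells["censored"], np.nan, cells["division_time"]),
                "n_frames": cells["n_frames"].to_numpy(),
                "mu": g["mu"],
                "sb": np.exp(g["y0"]),
                "sd": np.where(cells["censored"], np.nan, np.exp(g["y1"])),
                "var_log_sb": g["v0"],
                "var_log_sd": g["v1"],
                "cov_log_sb_sd": g["cov"],
                "censored": cells["censored"].to_numpy(),
                "zero_span": ~(g["sxx"] > 0),
            }
        )
        pieces.append(df)
    cycles = pd.concat(pieces, ignore_index=True)

    # groups with zero time spread cannot be fitted
    zero_span_keys = cycles.loc[cycles["zero_span"], ["colony_id", "cell_id"]].drop_duplicates()
    for _, r in zero_span_keys.iterrows():
        excl_rows.append((r["colony_id"], r["cell_id"], "zero_time_span"))
    if len(zero_span_keys):
        bad = pd.MultiIndex.from_frame(zero_span_keys)
        keep = ~pd.MultiIndex.from_frame(cycles[["colony_id", "cell_id"]]).isin(bad)
        cycles = cycles.loc[keep]
    cycles = cycles.drop(columns="zero_span")

    cycles["delta_d"] = cycles["sd"] - cycles["sb"]
    cycles["tau_d"] = cycles["division_time"] - cycles["birth_time"]
    exclusions = pd.DataFrame(excl_rows, columns=["colony_id", "cell_id", "reason"])
    exclusions.attrs["n_frames_bad_shape"] = n_bad_shape
    return cycles.reset_index(drop=True), exclusions


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class CorrelationResult:
    R: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def ci_contains_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


@dataclass(frozen=True)
class ProxySummary:
    """Table-2-style statistics of one size proxy, with 95% bootstrap CIs."""

    proxy: str
    mean_sb: float
    ci_mean_sb: tuple[float, float]
    cv2_sb: float
    ci_cv2_sb: tuple[float, float]
    mean_delta_d: float
    ci_mean_delta_d: tuple[float, float]
    cv2_delta_d: float
    ci_cv2_delta_d: tuple[float, float]
    pearson_R: float
    ci_pearson_R: tuple[float, float]
    mean_tau_d: float
    mean_mu: float
    ci_mean_mu: tuple[float, float]
    n_cycles: int
    n_newborns: int
    cv2_sb_raw: float
    cv2_delta_d_raw: float
    pearson_R_raw: float
    # colony-progenitor subset (drives the population-noise plateau)
    mean_sb_progenitor: float = float("nan")
    cv2_sb_progenitor: float = float("nan")
    ci_cv2_sb_progenitor: tuple[float, float] = (float("nan"), float("nan"))
    n_progenitors: int = 0

    @property
    def adder_consistent(self) -> bool:
        return self.ci_pearson_R[0] <= 0.0 <= self.ci_pearson_R[1]


@dataclass
class SizeRegulationSummary:
    proxies: Mapping[str, ProxySummary]
    boundary: str = "midpoint"
    corrected: bool = True
    exclusion_counts: Mapping[str, int] = field(default_factory=dict)

    def __getitem__(self, proxy: str) -> ProxySummary:
        return self.proxies[proxy]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.proxies.values():
            rows.append(
                {
                    "proxy": p.proxy,
                    "mean_sb": p.mean_sb,
                    "cv2_sb": p.cv2_sb,
                    "mean_delta_d": p.mean_delta_d,
                    "cv2_delta_d": p.cv2_delta_d,
                    "pearson_R": p.pearson_R,
                    "mean_tau_d": p.mean_tau_d,
                    "n_cycles": p.n_cycles,
                }
            )
        return pd.DataFrame(rows).set_index("proxy")


def _corrected_stats(sb, delta, vm_sb, vm_delta, cm_sb_delta):
    """Point estimates (corrected and raw) from per-cycle arrays."""
    mean_sb, mean_d = sb.mean(), delta.mean()
    var_sb, var_d = sb.var(ddof=1), delta.var(ddof=1)
    cov = float(np.cov(sb, delta, ddof=1)[0, 1])
    var_sb_c = max(var_sb - vm_sb.mean(), 1e-12)
    var_d_c = max(var_d - vm_delta.mean(), 1e-12)
    cov_c = cov - cm_sb_delta.mean()
    return {
        "mean_sb": mean_sb,
        "mean_delta": mean_d,
        "cv2_sb": var_sb_c / mean_sb**2,
        "cv2_delta": var_d_c / mean_d**2,
        "R": cov_c / np.sqrt(var_sb_c * var_d_c),
        "cv2_sb_raw": var_sb / mean_sb**2,
        "cv2_delta_raw": var_d / mean_d**2,
        "R_raw": cov / np.sqrt(var_sb * var_d),
    }


def newborn_and_added_size_summary(
    cycles: pd.DataFrame,
    n_boot: int = 1000,
    seed=None,
    frame_interval: float = 10.0,
    correct_measurement: bool = True,
    pool: str = "all",
) -> SizeRegulationSummary:
    """Per-proxy size-regulation statistics with bootstrap 95% CIs.

    ``pool="all"`` uses every fitted newborn for the s_b statistics;
    ``pool="progenitor"`` restricts them to colony progenitors.  Δd
    statistics and the Δd–s_b Pearson correlation use completed
    (non-censored) cycles; the bootstrap resampling unit is the cycle.

    With ``correct_measurement`` the mean propagated fit variance plus the
    boundary-jitter term (μΔt)²/12 per boundary is subtracted from the
    observed variances and covariance before forming CV² and R (see module
    docstring); raw plug-in values are kept in the ``*_raw`` fields.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for proxy in PROXIES:
        sub = cycles[cycles["proxy"] == proxy]
        comp = sub[~sub["censored"] & sub["delta_d"].notna() & (sub["delta_d"] > 0)]
        if len(comp) < 3:
            raise ValueError(f"not enough completed cycles for proxy {proxy!r}")
        newborns = sub if pool == "all" else sub[sub["parent_id"] == PROGENITOR_PARENT]

        sb = comp["sb"].to_numpy(float)
        sd = comp["sd"].to_numpy(float)
        delta = comp["delta_d"].to_numpy(float)
        mu = comp["mu"].to_numpy(float)
        zero = np.zeros_like(sb)
        if correct_measurement:
            jit = (mu * frame_interval) ** 2 / 12.0
            # progenitors are synchronised to the movie start: their birth
            # carries no frame-localisation jitter, only their division does
            jit_b = np.where(comp["parent_id"].to_numpy() == PROGENITOR_PARENT, 0.0, jit)
            vlb = comp["var_log_sb"].to_numpy(float) + jit_b
            vld = comp["var_log_sd"].to_numpy(float) + jit
            clbd = comp["cov_log_sb_sd"].to_numpy(float)
            vm_sb = sb**2 * vlb
            vm_delta = sd**2 * vld + sb**2 * vlb - 2 * sb * sd * clbd
            cm = sb * sd * clbd - sb**2 * vlb
        else:
            vm_sb = vm_delta = cm = zero

        # newborn pool for s_b level statistics (may include censored cells)
        def _sb_arrays(df):
            v = df["sb"].to_numpy(float)
            if correct_measurement:
                j = (df["mu"].to_numpy(float) * frame_interval) ** 2 / 12.0
                j = np.where(df["parent_id"].to_numpy() == PROGENITOR_PARENT, 0.0, j)
                vm = v**2 * (df["var_log_sb"].to_numpy(float) + j)
            else:
                vm = np.zeros_like(v)
            return v, vm

        sbn, vmn = _sb_arrays(newborns)
        prog = sub[sub["parent_id"] == PROGENITOR_PARENT]
        sbp, vmp = _sb_arrays(prog)

        pt = _corrected_stats(sb, delta, vm_sb, vm_delta, cm)
        mean_sbn = sbn.mean()
        var_sbn_c = max(sbn.var(ddof=1) - vmn.mean(), 1e-12)
        cv2_sbn = var_sbn_c / mean_sbn**2
        cv2_sbn_raw = sbn.var(ddof=1) / mean_sbn**2

        boot = {
            k: np.empty(n_boot)
            for k in ("mean_sb", "cv2_sb", "mean_delta", "cv2_delta", "R", "mu", "cv2_sb_prog")
        }
        nn, nc, npr = sbn.size, sb.size, sbp.size
        for b in range(n_boot):
            i = rng.integers(0, nn, nn)
            m = sbn[i].mean()
            boot["mean_sb"][b] = m
            boot["cv2_sb"][b] = max(sbn[i].var(ddof=1) - vmn[i].mean(), 1e-12) / m**2
            j = rng.integers(0, nc, nc)
            s = _corrected_stats(sb[j], delta[j], vm_sb[j], vm_delta[j], cm[j])
            boot["mean_delta"][b] = s["mean_delta"]
            boot["cv2_delta"][b] = s["cv2_delta"]
            boot["R"][b] = s["R"]
            boot["mu"][b] = mu[j].mean()
            if npr >= 2:
                k2 = rng.integers(0, npr, npr)
                boot["cv2_sb_prog"][b] = max(
                    sbp[k2].var(ddof=1) - vmp[k2].mean(), 1e-12
                ) / sbp[k2].mean() ** 2
            else:
                boot["cv2_sb_prog"][b] = np.nan

        def ci(k):
            lo, hi = np.quantile(boot[k], [0.025, 0.975])
            return (float(lo), float(hi))

        out[proxy] = ProxySummary(
            proxy=proxy,
            mean_sb=float(mean_sbn),
            ci_mean_sb=ci("mean_sb"),
            cv2_sb=float(cv2_sbn),
            ci_cv2_sb=ci("cv2_sb"),
            mean_delta_d=float(pt["mean_delta"]),
            ci_mean_delta_d=ci("mean_delta"),
            cv2_delta_d=float(pt["cv2_delta"]),
            ci_cv2_delta_d=ci("cv2_delta"),
            pearson_R=float(pt["R"]),
            ci_pearson_R=ci("R"),
            mean_tau_d=float(comp["tau_d"].mean()),
            mean_mu=float(mu.mean()),
            ci_mean_mu=ci("mu"),
            n_cycles=int(nc),
            n_newborns=int(nn),
            cv2_sb_raw=float(cv2_sbn_raw),
            cv2_delta_d_raw=float(pt["cv2_delta_raw"]),
            pearson_R_raw=float(pt["R_raw"]),
            mean_sb_progenitor=float(sbp.mean()) if npr else float("nan"),
            cv2_sb_progenitor=(
                float(max(sbp.var(ddof=1) - vmp.mean(), 1e-12) / sbp.mean() ** 2)
                if npr >= 2
                else float("nan")
            ),
            ci_cv2_sb_progenitor=ci("cv2_sb_prog") if npr >= 2 else (float("nan"),) * 2,
            n_progenitors=int(npr),
        )
    return SizeRegulationSummary(proxies=out, corrected=correct_measurement)


def division_strategy_correlation(
    pairs: Sequence[tuple[float, float]],
    n_boot: int = 1000,
    seed=None,
) -> CorrelationResult:
    """Pearson R between s_b and Δd with a percentile-bootstrap 95% CI.

    The adder predicts Δd independent of s_b, hence R ≈ 0; the verdict is
    ``result.ci_contains_zero``.  Sizer-like regulation gives R → −1,
    timer-like R > 0.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (sb, delta_d) tuples")
    if arr.shape[0] < 10:
        raise ValueError(f"need at least 10 pairs, got {arr.shape[0]}")
    sb, dd = arr[:, 0], arr[:, 1]
    if np.ptp(sb) == 0 or np.ptp(dd) == 0:
        raise ValueError("constant sb or delta_d: correlation undefined")
    from scipy.stats import pearsonr

    R = float(pearsonr(sb, dd).statistic)
    rng = np.random.default_rng(seed)
    n = sb.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        i = rng.integers(0, n, n)
        x, y = sb[i], dd[i]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            boots[b] = np.nan
            continue
        boots[b] = pearsonr(x, y).statistic
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return CorrelationResult(R=R, ci_low=float(lo), ci_high=float(hi), n=n)


def lineage_correlations(
    cycles: pd.DataFrame, proxy: str = "area", n_boot: int = 1000, seed=None
) -> dict:
    """Mother–daughter and sister correlations of the added size Δd.

    Each unordered sister pair contributes once in both orders.  Pairs with
    unresolvable parent links are skipped and counted in ``n_skipped``.
    """
    sub = cycles[(cycles["proxy"] == proxy) & ~cycles["censored"] & cycles["delta_d"].notna()]
    by_key = sub.set_index(["colony_id", "cell_id"])["delta_d"]

    md, skipped = [], 0
    children = sub[sub["parent_id"] != PROGENITOR_PARENT]
    for _, r in children.iterrows():
        key = (r["colony_id"], r["parent_id"])
        if key in by_key.index:
            md.append((by_key.loc[key], r["delta_d"]))
        else:
            skipped += 1

    sis = []
    for (_, _), grp in children.groupby(["colony_id", "parent_id"]):
        if len(grp) == 2:
            d1, d2 = grp["delta_d"].to_numpy()
            sis.append((d1, d2))
            sis.append((d2, d1))

    out = {"n_skipped": skipped}
    for name, pairs in (("mother_daughter", md), ("sister", sis)):
        if len(pairs) >= 10:
            out[name] = division_strategy_correlation(pairs, n_boot=n_boot, seed=seed)
        else:
            out[name] = None
    return out


def cycle_phase_noise(
    frames: pd.DataFrame,
    cycles: pd.DataFrame,
    n_bins: int = 8,
    min_per_bin: int = 20,
    n_boot: int = 200,
    seed=None,
) -> pd.DataFrame:
    """Dimension noise (CV² of L, A, V) versus time since last division.

    ``frames`` must be shape-annotated; time since division is the frame
    time minus the cell's reconstructed birth time.  Bins are equal-width in
    minutes; bins with fewer than ``min_per_bin`` cells are merged into
    their left neighbour (the merge count is in ``df.attrs["n_merged"]``).
    Per-bin 95% bootstrap CIs resample cells within the bin.
    """
    births = (
        cycles[cycles["proxy"] == "length"]
        .set_index(["colony_id", "cell_id"])["birth_time"]
    )
    key = pd.MultiIndex.from_frame(frames[["colony_id", "cell_id"]])
    tsd = frames["time_min"].to_numpy(float) - births.reindex(key).to_numpy(float)
    ok = np.isfinite(tsd) & (tsd >= 0)
    sub = frames.loc[ok]
    tsd = tsd[ok]

    edges = np.linspace(0.0, tsd.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(tsd, edges) - 1, 0, n_bins - 1)
    # merge underfilled bins leftward
    counts = np.bincount(idx, minlength=n_bins)
    mapping = np.arange(n_bins)
    n_merged = 0
    for b in range(1, n_bins):
        tgt = mapping[b]
        if counts[tgt] and counts[tgt] < min_per_bin:
            prev = mapping[b - 1]
            mapping[mapping == tgt] = prev
            counts[prev] += counts[tgt]
            counts[tgt] = 0
            n_merged += 1
    idx = mapping[idx]

    rng = np.random.default_rng(seed)
    rows = []
    for b in np.unique(idx):
        m = idx == b
        if m.sum() < 2:
            continue
        row = {
            "bin_left": edges[b],
            "bin_right": edges[int(np.max(np.where(mapping == b))) + 1],
            "n": int(m.sum()),
        }
        for proxy, col in PROXIES.items():
            v = sub.loc[m, col].to_numpy(float)
            cv2 = v.var(ddof=1) / v.mean() ** 2
            bs = np.empty(n_boot)
            for k in range(n_boot):
                i = rng.integers(0, v.size, v.size)
                bs[k] = v[i].var(ddof=1) / v[i].mean() ** 2
            lo, hi = np.quantile(bs, [0.025, 0.975])
            row[f"cv2_{proxy}"] = cv2
            row[f"cv2_{proxy}_lo"] = lo
            row[f"cv2_{proxy}_hi"] = hi
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_merged"] = n_merged
    return df
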