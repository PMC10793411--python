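"""Model/Results interface for size-regulation analysis of lineage tables.

`SizeRegulationModel` wraps the full reconstruction pipeline the way a
statsmodels model wraps a design matrix: construct it from a frame-level
lineage table, call :meth:`~SizeRegulationModel.fit`, and get a
`SizeRegulationResults` carrying per-proxy estimates (newborn and added
size means, their squared CVs, the adder correlation R) with bootstrap
CIs, per-cycle records, exclusion accounting, and a ``summary()`` table.
Proxy comparison against the observed colony-count dynamics hangs off the
results object (:meth:`SizeRegulationResults.compare_proxies`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import growth
from .growth import PROXIES, SizeRegulationSummary
from .population import EnsembleStats

__all__ = ["SizeRegulationModel", "SizeRegulationResults"]


class SizeRegulationModel:
    """Cell-size-regulation model for a segmented time-lapse lineage table.

    Parameters
    ----------
    table:
        Frame-level lineage table (``colony_id, cell_id, parent_id,
        time_min, length_um, projected_area_um2``; parent −1 = progenitor).
    boundary:
        Cycle-boundary convention, ``"midpoint"`` (default) or ``"frame"``.
    min_frames:
        Minimum frames per cycle for the exponential fit.
    pool_newborns:
        ``"all"`` (default) pools every newborn for the s_b statistics;
        ``"progenitor"`` restricts to colony progenitors.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        boundary: str = "midpoint",
        min_frames: int = 3,
        frame_interval: float | None = None,
        pool_newborns: str = "all",
    ):
        self.table = growth.validate_lineage_table(table)
        self.boundary = boundary
        self.min_frames = min_frames
        self.pool_newborns = pool_newborns
        if frame_interval is None:
            diffs = (
                table.sort_values("time_min")
                .groupby(["colony_id", "cell_id"])["time_min"]
                .diff()
                .dropna()
            )
            frame_interval = float(diffs.median()) if len(diffs) else 10.0
        self.frame_interval = frame_interval

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SizeRegulationModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(
        self,
        n_boot: int = 1000,
        seed=None,
        correct_measurement: bool = True,
    ) -> "SizeRegulationResults":
        """Reconstruct cycles and estimate the size-regulation statistics."""
        cycles, exclusions = growth.reconstruct_cycles(
            self.table,
            boundary=self.boundary,
            min_frames=self.min_frames,
            frame_interval=self.frame_interval,
        )
        summary = growth.newborn_and_added_size_summary(
            cycles,
            n_boot=n_boot,
            seed=seed,
            frame_interval=self.frame_interval,
            correct_measurement=correct_measurement,
            pool=self.pool_newborns,
        )
        summary.boundary = self.boundary
        counts = exclusions["reason"].value_counts().to_dict() if len(exclusions) else {}
        summary.exclusion_counts = counts
        return SizeRegulationResults(
            model=self, cycles=cycles, exclusions=exclusions, summaries=summary
        )


@dataclass
class SizeRegulationResults:
    """Fitted size-regulation statistics with bootstrap uncertainties."""

    model: SizeRegulationModel
    cycles: pd.DataFrame
    exclusions: pd.DataFrame
    summaries: SizeRegulationSummary
    _observed: EnsembleStats | None = field(default=None, repr=False)

    def __getitem__(self, proxy: str):
        return self.summaries[proxy]

    @property
    def params(self) -> pd.DataFrame:
        """Point estimates as a per-proxy DataFrame."""
        return self.summaries.to_frame()

    def observed_population(
        self, n_boot: int = 1000, seed=None, min_tracked_fraction: float = 0.9
    ) -> EnsembleStats:
        """⟨N(t)⟩ and CV²_N(t) of the observed colonies with bootstrap CIs."""
        from .pipeline import observed_population_stats

        self._observed = observed_population_stats(
            self.model.table,
            n_boot=n_boot,
            seed=seed,
            min_tracked_fraction=min_tracked_fraction,
        )
        return self._observed

    def compare_proxies(self, seed=0, n_colonies_factor: int = 10, n_boot: int = 500):
        """Simulate matched adder ensembles per proxy and rank them by fit
        to the observed CV²_N(t) dynamics."""
        from .pipeline import compare

        observed = self._observed or self.observed_population(n_boot=n_boot, seed=seed)
        return compare(
            self.summaries, observed, seed=seed, n_colonies_factor=n_colonies_factor
        )

    def lineage_correlations(self, proxy: str = "area", n_boot: int = 1000, seed=None):
        return growth.lineage_correlations(self.cycles, proxy=proxy, n_boot=n_boot, seed=seed)

    def summary(self):
        """Human-readable estimation summary (statsmodels-style table)."""
        from statsmodels.iolib.table import SimpleTable

        rows = []
        for name, p in self.summaries.proxies.items():
            rows.append(
                [
                    name,
                    f"{p.mean_sb:.3f}",
                    f"{p.cv2_sb:.4f}",
                    f"{p.mean_delta_d:.3f}",
                    f"{p.cv2_delta_d:.4f}",
                    f"{p.pearson_R:+.3f}",
                    f"[{p.ci_pearson_R[0]:+.3f}, {p.ci_pearson_R[1]:+.3f}]",
                    f"{p.n_cycles}",
                ]
            )
        headers = ["proxy", "mean s_b", "CV²_sb", "mean Δd", "CV²_Δd", "R(Δd,s_b)", "R 95% CI", "n"]
        any_p = next(iter(self.summaries.proxies.values()))
        title = (
            "Cell size regulation summary "
            f"(τ̄d = {any_p.mean_tau_d:.1f} min, boundary={self.summaries.boundary}, "
            f"{'corrected' if self.summaries.corrected else 'raw'} moments)"
        )
        tbl = SimpleTable(rows, headers=headers, title=title)
        return tbl

    def __str__(self) -> str:
        return str(self.summary())
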