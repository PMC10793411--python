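"""Cycle reconstruction, exponential fits, size-regulation statistics."""

import numpy as np
import pandas as pd
import pytest

from colonystats import (
    CycleFitError,
    GeneratorParams,
    SizeRegulationModel,
    division_strategy_correlation,
    fit_exponential_growth,
    generate_dataset,
)
from colonystats.growth import (
    PROXIES,
    annotate_shapes,
    cycle_phase_noise,
    lineage_correlations,
    newborn_and_added_size_summary,
    reconstruct_cycles,
)

LN2 = float(np.log(2.0))


class TestExponentialFit:
    def test_exact_log_linear_data(self):
        t = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        s = 2.0 * np.exp(0.01 * t)
        fit = fit_exponential_growth(np.c_[t, s], birth_time=0.0, division_time=50.0)
        assert fit.mu == pytest.approx(0.01, rel=1e-9)
        assert fit.sb == pytest.approx(2.0, rel=1e-9)
        assert fit.sd == pytest.approx(2.0 * np.exp(0.5), rel=1e-9)

    def test_tuple_unpacking(self):
        t = np.array([0.0, 10.0, 20.0])
        mu, sb, sd = fit_exponential_growth(np.c_[t, np.exp(0.02 * t)], 0.0, 20.0)
        assert mu == pytest.approx(0.02, rel=1e-9)

    def test_noisy_recovery_error_distribution(self):
        # 3% multiplicative noise, 8 frames: the median relative error of
        # mu over 1000 replicates stays well inside 15%
        rng = np.random.default_rng(77)
        t = np.arange(0.0, 80.0, 10.0)
        errs = []
        for _ in range(1000):
            s = 2.0 * np.exp(0.01 * t) * rng.lognormal(0.0, 0.03, t.size)
            fit = fit_exponential_growth(np.c_[t, s], 0.0, 75.0)
            errs.append(abs(fit.mu - 0.01) / 0.01)
        assert np.median(errs) < 0.15

    def test_reason_codes(self):
        t = np.array([0.0, 10.0, 20.0])
        with pytest.raises(CycleFitError) as e:
            fit_exponential_growth(np.c_[t, [1.0, 0.0, 2.0]], 0.0, 20.0)
        assert e.value.reason == "nonpositive_size"
        with pytest.raises(CycleFitError) as e:
            fit_exponential_growth([(0.0, 1.0), (10.0, 2.0)], 0.0, 10.0)
        assert e.value.reason == "too_few_frames"
        with pytest.raises(CycleFitError) as e:
            fit_exponential_growth(np.c_[t, [1.0, 2.0, 3.0]], 5.0, 5.0)
        assert e.value.reason == "zero_time_span"


class TestStrategyCorrelation:
    def test_adder_null_gives_zero_correlation(self):
        rng = np.random.default_rng(42)
        sb = rng.gamma(40, 1 / 40, 3000)
        dd = rng.gamma(17, 1 / 17, 3000)  # independent of sb: the adder null
        res = division_strategy_correlation(np.c_[sb, dd], seed=1)
        assert abs(res.R) < 0.05
        assert res.ci_contains_zero

    def test_sizer_like_data_fully_anticorrelated(self):
        rng = np.random.default_rng(0)
        sb = rng.uniform(0.5, 1.5, 200)
        res = division_strategy_correlation(np.c_[sb, 2.0 - sb], seed=1)
        assert res.R == pytest.approx(-1.0, abs=1e-12)
        assert not res.ci_contains_zero

    def test_timer_like_data_positively_correlated(self):
        rng = np.random.default_rng(3)
        sb = np.exp(rng.normal(0.0, 0.2, 3000))
        tau = rng.gamma(25, 1 / 25, 3000)  # independent cycle times
        delta = sb * (np.exp(LN2 * tau) - 1.0)
        res = division_strategy_correlation(np.c_[sb, delta], seed=1)
        assert res.R > 0.5
        assert res.ci_low > 0

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(ValueError):
            division_strategy_correlation([(1.0, 2.0)] * 20)
        with pytest.raises(ValueError):
            division_strategy_correlation([(1.0, 2.0)] * 5 + [(2.0, 3.0)] * 3)


class TestLineageCorrelations:
    @staticmethod
    def _cycles_from_deltas(deltas_by_cell):
        rows = []
        for (colony, cell, parent), dd in deltas_by_cell.items():
            rows.append(
                dict(
                    colony_id=colony,
                    cell_id=cell,
                    parent_id=parent,
                    proxy="area",
                    delta_d=dd,
                    censored=False,
                )
            )
        return pd.DataFrame(rows)

    def test_independent_deltas_uncorrelated(self):
        rng = np.random.default_rng(10)
        cells = {}
        cid = 0
        for colony in range(1000):
            cells[(colony, 0, -1)] = rng.gamma(20, 1 / 20)
            cells[(colony, 1, 0)] = rng.gamma(20, 1 / 20)
            cells[(colony, 2, 0)] = rng.gamma(20, 1 / 20)
        out = lineage_correlations(self._cycles_from_deltas(cells), seed=4)
        assert abs(out["mother_daughter"].R) < 0.06
        assert abs(out["sister"].R) < 0.06

    def test_shared_sister_component_recovered(self):
        # sisters share a common noise component carrying rho of the variance
        rng = np.random.default_rng(11)
        rho = 0.4
        cells = {}
        for colony in range(1500):
            cells[(colony, 0, -1)] = 1.0 + 0.1 * rng.standard_normal()
            shared = np.sqrt(rho) * rng.standard_normal()
            for k in (1, 2):
                own = np.sqrt(1 - rho) * rng.standard_normal()
                cells[(colony, k, 0)] = 5.0 + shared + own
        out = lineage_correlations(self._cycles_from_deltas(cells), seed=4)
        assert out["sister"].ci_low <= rho <= out["sister"].ci_high

    def test_single_generation_plumbing(self):
        rng = np.random.default_rng(1)
        cells = {}
        for colony in range(30):
            cells[(colony, 0, -1)] = rng.gamma(20, 1 / 20)
            cells[(colony, 1, 0)] = rng.gamma(20, 1 / 20)
            cells[(colony, 2, 0)] = rng.gamma(20, 1 / 20)
        out = lineage_correlations(self._cycles_from_deltas(cells), seed=0)
        assert out["mother_daughter"] is not None
        assert out["sister"] is not None
        assert out["n_skipped"] == 0


class TestReconstruction:
    def test_filter_accounting_no_silent_drops(self, small_table):
        cycles, excl = reconstruct_cycles(small_table.frames)
        n_cells_fitted = cycles.groupby("proxy")["cell_id"].size().iloc[0]
        n_candidates = small_table.frames.groupby(["colony_id", "cell_id"]).ngroups
        assert n_cells_fitted + len(excl) == n_candidates

    def test_censored_cells_have_no_delta(self, small_table):
        cycles, _ = reconstruct_cycles(small_table.frames)
        cens = cycles[cycles["censored"]]
        assert len(cens) > 0
        assert cens["delta_d"].isna().all()
        assert cens["sb"].notna().all()

    def test_noiseless_frame_aligned_round_trip(self):
        # all noise off and the doubling time a multiple of the frame
        # interval: divisions land exactly on frames, so the frame-boundary
        # convention recovers mu and every added size to numerical precision
        params = GeneratorParams(
            doubling_time_min=80.0,
            mean_sb=4.75,
            cv2_sb=0.0,
            cv2_delta_d=0.0,
            cv2_w=0.0,
            cv_meas=0.0,
            n_colonies=3,
            max_generations=3,
            seed=1,
        )
        tab = generate_dataset(params)
        cycles, _ = reconstruct_cycles(tab.frames, boundary="frame")
        area = cycles[(cycles["proxy"] == "area") & ~cycles["censored"]]
        assert np.allclose(area["mu"], params.growth_rate_mu, rtol=1e-9)
        assert np.allclose(area["delta_d"], params.mean_delta_d, rtol=1e-9)

    def test_nonpositive_sizes_excluded_with_reason(self, small_table):
        frames = small_table.frames.copy()
        victim = frames.iloc[0][["colony_id", "cell_id"]]
        m = (frames["colony_id"] == victim["colony_id"]) & (
            frames["cell_id"] == victim["cell_id"]
        )
        frames.loc[frames[m].index[0], "length_um"] = 0.0
        _, excl = reconstruct_cycles(frames)
        reasons = excl.set_index(["colony_id", "cell_id"])["reason"]
        assert reasons.loc[(victim["colony_id"], victim["cell_id"])] == "nonpositive_size"

    def test_shape_annotation_drops_impossible_frames(self, small_table):
        # a handful of near-spherical frames are already inconsistent after
        # measurement noise; corrupting one more drops exactly one more
        _, n_bad_baseline = annotate_shapes(small_table.frames)
        frames = small_table.frames.copy()
        frames.loc[frames.index[0], "projected_area_um2"] = 1e6  # no capsule fits
        annotated, n_bad = annotate_shapes(frames)
        assert n_bad == n_bad_baseline + 1
        assert len(annotated) == len(frames) - n_bad
        assert (annotated["width_um"] <= annotated["length_um"] * (1 + 1e-9)).all()


class TestSummary:
    def test_recovery_against_ground_truth_pool(self, small_table, small_fit):
        # the corrected estimates match moments of the true sizes of the
        # very same cells (pool-matched comparison, n = 12 colonies)
        cycles = small_fit.cycles
        truth = small_table.ground_truth
        merged = cycles[cycles["proxy"] == "area"].merge(
            truth, on=["colony_id", "cell_id"], suffixes=("", "_gt")
        )
        p = small_fit["area"]
        sb_true = merged["sb_true"]
        cv2_true = sb_true.var(ddof=1) / sb_true.mean() ** 2
        assert p.cv2_sb == pytest.approx(cv2_true, rel=0.25)
        comp = merged[~merged["censored"]]
        dd_true = comp["delta_d_true"]
        assert p.mean_delta_d == pytest.approx(dd_true.mean(), rel=0.02)
        assert p.cv2_delta_d == pytest.approx(
            dd_true.var(ddof=1) / dd_true.mean() ** 2, rel=0.30
        )

    def test_correction_removes_inflation(self, small_fit):
        for proxy in PROXIES:
            p = small_fit[proxy]
            assert p.cv2_delta_d < p.cv2_delta_d_raw
            assert p.pearson_R > p.pearson_R_raw  # raw R is biased downward

    def test_steady_state_sb_noise_is_a_third_of_delta_noise(self):
        # stationary-start population snapshot: CV²_sb ≈ CV²_Δd / 3
        params = GeneratorParams(
            mean_sb=4.75, cv2_sb=0.058 / 3, n_colonies=60, seed=8
        )
        tab = generate_dataset(params)
        res = SizeRegulationModel(tab.frames).fit(n_boot=150, seed=0)
        p = res["area"]
        assert p.cv2_delta_d / p.cv2_sb == pytest.approx(3.0, rel=0.20)

    def test_noiseless_population_has_zero_cv2(self):
        params = GeneratorParams(
            doubling_time_min=80.0,
            mean_sb=4.75,
            cv2_sb=0.0,
            cv2_delta_d=0.0,
            cv2_w=0.0,
            cv_meas=0.0,
            n_colonies=3,
            max_generations=3,
            seed=2,
        )
        tab = generate_dataset(params)
        cycles, _ = reconstruct_cycles(tab.frames, boundary="frame")
        summ = newborn_and_added_size_summary(cycles, n_boot=120, seed=0)
        for proxy in PROXIES:
            assert summ[proxy].cv2_delta_d < 1e-6
            assert summ[proxy].cv2_sb < 1e-6

    def test_adder_correlation_small_on_adder_data(self, small_fit):
        # ~750 cycles: the corrected R should sit within sampling noise of 0
        p = small_fit["area"]
        assert abs(p.pearson_R) < 0.12
        ci_lo, ci_hi = p.ci_pearson_R
        assert ci_lo < 0.05 and ci_hi > -0.05  # interval brackets (near) zero


class TestCyclePhaseNoise:
    def test_ordering_with_length_governed_widths(self):
        # length-governed adder with independent width noise: the dimension
        # noise must order as length < area < volume in every bin
        params = GeneratorParams(
            governing_proxy="length",
            mean_delta_d=1.526,
            cv2_delta_d=0.042,
            mean_sb=1.882,
            cv2_sb=0.0147,
            n_colonies=40,
            seed=5,
        )
        tab = generate_dataset(params)
        frames, _ = annotate_shapes(tab.frames)
        cycles, _ = reconstruct_cycles(tab.frames)
        df = cycle_phase_noise(frames, cycles, n_bins=6, seed=0)
        assert len(df) >= 3
        assert (df["cv2_length"] < df["cv2_area"]).all()
        assert (df["cv2_area"] < df["cv2_volume"]).all()

    def test_decreasing_width_noise_lowers_late_cycle_volume_noise(self):
        params = GeneratorParams(
            governing_proxy="length",
            mean_delta_d=1.526,
            cv2_delta_d=0.042,
            mean_sb=1.882,
            cv2_sb=0.0147,
            n_colonies=40,
            width_noise_slope=-1.6,
            seed=6,
        )
        tab = generate_dataset(params)
        frames, _ = annotate_shapes(tab.frames)
        cycles, _ = reconstruct_cycles(tab.frames)
        df = cycle_phase_noise(frames, cycles, n_bins=6, seed=0)
        assert df["cv2_volume"].iloc[0] > df["cv2_volume"].iloc[-1]

    def test_zero_noise_zero_cv2(self):
        params = GeneratorParams(
            doubling_time_min=80.0,
            mean_sb=4.75,
            cv2_sb=0.0,
            cv2_delta_d=0.0,
            cv2_w=0.0,
            cv_meas=0.0,
            n_colonies=4,
            max_generations=3,
            seed=3,
        )
        tab = generate_dataset(params)
        frames, _ = annotate_shapes(tab.frames)
        cycles, _ = reconstruct_cycles(tab.frames, boundary="frame")
        # 8 bins over an 80-min cycle sampled every 10 min: one frame offset
        # per bin, so with all noise off every bin is exactly monodisperse
        df = cycle_phase_noise(frames, cycles, n_bins=8, min_per_bin=2, seed=0)
        for proxy in PROXIES:
            assert (df[f"cv2_{proxy}"] < 1e-9).all()
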