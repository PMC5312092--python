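"""Growth fitting/classification and event detection/summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from gliamet.dynamics import (GROWTH, NO_CHANGE, SHRINKAGE, CellGrowthModel,
                              InsufficientDataError, ParameterError,
                              classify_growth, detect_events, fit_area_series,
                              fit_growth, summarize_dynamics)
from gliamet.geometry import ContourSeries, validate_contour
from gliamet.synthetic import generate_area_series, generate_cell_series, wt_params


def square_series(areas, cell_id="c"):
    """Series of axis-aligned squares with the prescribed areas."""
    contours = []
    for t, a in enumerate(areas):
        s = np.sqrt(a)
        contours.append(validate_contour(
            [(0, 0), (s, 0), (s, s), (0, s)], cell_id=cell_id, t=float(t)))
    return ContourSeries(contours)


class TestFitGrowth:
    def test_exact_line(self):
        series = square_series(np.arange(100, 142, 2))  # 100..140 at t=0..20
        fit = fit_growth(series, window_min=20)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.p_slope < 1e-100
        assert fit.n_frames == 21

    def test_constant_series(self):
        fit = fit_growth(square_series([50.0] * 21), window_min=20)
        assert fit.slope == 0.0
        assert fit.r == 0.0
        assert fit.p_slope == 1.0
        assert fit.classify() == NO_CHANGE

    def test_matches_linregress_oracle(self):
        t, areas = generate_area_series(slope=1.5, sigma=2.0, n=21, seed=7)
        fit = fit_area_series(t, areas)
        ref = sps.linregress(t, areas)
        assert fit.slope == pytest.approx(ref.slope, abs=1e-10)
        assert fit.intercept == pytest.approx(ref.intercept, abs=1e-10)
        assert fit.r == pytest.approx(ref.rvalue, abs=1e-10)
        assert fit.p_slope == pytest.approx(ref.pvalue, abs=1e-10)

    def test_window_selection(self):
        series = square_series(np.arange(100, 181, 1))  # 81 frames
        fit = fit_growth(series, window_min=75)
        assert fit.n_frames == 76
        assert fit.window == (0.0, 75.0)

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            fit_growth(square_series([1, 2]), window_min=20)

    def test_sign_consistency(self):
        """sign(slope) == sign(r) whenever both are nonzero."""
        for seed in range(20):
            t, a = generate_area_series(slope=0.0, sigma=3.0, seed=seed)
            fit = fit_area_series(t, a)
            if fit.slope != 0 and fit.r != 0:
                assert np.sign(fit.slope) == np.sign(fit.r)

    def test_summary_mentions_slope(self):
        fit = fit_growth(square_series(np.arange(100, 142, 2)))
        assert "slope" in fit.summary()


class TestClassifyGrowth:
    def test_perfect_rising_line_is_growth(self):
        fit = fit_growth(square_series(np.arange(100, 142, 2)))
        assert classify_growth(fit) == GROWTH

    def test_alpha_validation(self):
        fit = fit_growth(square_series(np.arange(100, 142, 2)))
        for alpha in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(ParameterError):
                classify_growth(fit, alpha=alpha)

    def test_strong_negative_slope_is_shrinkage(self):
        """slope -3, sigma 1, n 21: essentially always shrinkage."""
        hits = 0
        for seed in range(200):
            t, a = generate_area_series(slope=-3.0, sigma=1.0, n=21,
                                        intercept=400.0, seed=seed)
            if fit_area_series(t, a).classify() == SHRINKAGE:
                hits += 1
        assert hits >= 198  # >= 99%


class TestDetectEvents:
    def test_identical_contours(self, unit_square):
        ev = detect_events(unit_square, unit_square)
        assert ev.n_extensions == 0 and ev.n_retractions == 0
        assert ev.net_area_change == pytest.approx(0.0)

    def test_single_constructed_bump(self):
        a = validate_contour([(0, 0), (1, 0), (1, 1), (0, 1)], t=0)
        b = validate_contour(
            [(0, 0), (1, 0), (1, 1), (0.65, 1), (0.65, 1.3),
             (0.35, 1.3), (0.35, 1), (0, 1)], t=1)
        ev = detect_events(a, b, min_area=0.05)
        assert ev.n_extensions == 1 and ev.n_retractions == 0
        assert ev.extensions[0].area == pytest.approx(0.09)

    def test_min_area_filter_drops_small_components(self, unit_square):
        a = unit_square
        b = unit_square.translated(0.01, 0.0)  # two 0.01-um^2 slivers
        ev = detect_events(a, b, min_area=0.1)
        assert ev.n_extensions == 0 and ev.n_retractions == 0
        # conservation is still evaluated on the unfiltered decomposition
        assert abs(ev.conservation_error) < 1e-9

    def test_recovers_injected_events(self):
        """Every injected generator event appears with matching area (2%)."""
        series, log = generate_cell_series(wt_params(seed=42))
        for i in range(series.n_frames - 1):
            ev = detect_events(series[i], series[i + 1])
            det_ext = sorted(c.area for c in ev.extensions)
            det_ret = sorted(c.area for c in ev.retractions)
            inj_ext = sorted(e.area for e in log.for_transition(i)
                             if e.sign == "extension")
            inj_ret = sorted(e.area for e in log.for_transition(i)
                             if e.sign == "retraction")
            assert len(det_ext) == len(inj_ext)
            assert len(det_ret) == len(inj_ret)
            assert det_ext == pytest.approx(inj_ext, rel=0.02)
            assert det_ret == pytest.approx(inj_ret, rel=0.02)


class TestSummarizeDynamics:
    def test_no_events_flags_means_absent(self):
        series = square_series([100.0] * 21)
        d = summarize_dynamics(series, window=20)
        assert d.ext_per_min == 0.0 and d.ret_per_min == 0.0
        assert d.mean_ext_size is None and d.mean_ret_size is None

    def test_window_longer_than_series(self):
        with pytest.raises(InsufficientDataError):
            summarize_dynamics(square_series([1, 2, 3]), window=20)

    def test_rigid_motion_invariance(self):
        series, _ = generate_cell_series(wt_params(seed=5, n_frames=11))
        d0 = summarize_dynamics(series, window=10)
        moved = series.transformed(dx=17.0, dy=-4.0, angle_rad=0.7)
        d1 = summarize_dynamics(moved, window=10)
        assert d1.ext_per_min == pytest.approx(d0.ext_per_min)
        assert d1.ret_per_min == pytest.approx(d0.ret_per_min)
        assert d1.mean_ext_size == pytest.approx(d0.mean_ext_size, rel=1e-6)
        assert d1.mean_ret_size == pytest.approx(d0.mean_ret_size, rel=1e-6)

    def test_rate_and_size_recovery(self):
        """Rates near the Poisson truth; mean sizes near the lognormal mean."""
        p = wt_params(size_sigma=0.4)
        ext_rates, ext_sizes = [], []
        for seed in range(40):
            series, _ = generate_cell_series(wt_params(seed=seed))
            d = summarize_dynamics(series, window=20)
            ext_rates.append(d.ext_per_min)
            if d.mean_ext_size is not None:
                ext_sizes.append(d.mean_ext_size)
        # SE of the rate over 40 cells x 20 min of Poisson(0.5/min) events
        se_rate = np.sqrt(0.5 / (40 * 20))
        assert np.mean(ext_rates) == pytest.approx(0.5, abs=3 * se_rate)
        analytic_mean = p.ext_size_median * np.exp(p.size_sigma**2 / 2)
        sizes = np.array(ext_sizes)
        se_size = sizes.std(ddof=1) / np.sqrt(len(sizes))
        assert sizes.mean() == pytest.approx(analytic_mean, abs=3 * se_size)


class TestCellGrowthModel:
    def test_model_front_door_matches_functions(self):
        series, _ = generate_cell_series(wt_params(seed=9))
        model = CellGrowthModel(series)
        assert model.fit().slope == fit_growth(series).slope
        assert model.dynamics().ext_per_min == summarize_dynamics(series).ext_per_min
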