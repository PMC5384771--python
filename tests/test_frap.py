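import numpy as np
import pytest

from sypflux.frap import (
    AnalysisConfig,
    RecoveryCurve,
    fit_recovery,
    plateau,
    position_and_stage,
    reference_normalized_total,
    strong_recovery_call,
    sum_projection,
)
from sypflux.geometry import EllipseROI, GeometryError, RectangleROI
from sypflux.kinetics import closed_form_extent
from sypflux.render import ImagingParams, TimeSeriesStack, geometry_for_radius
from sypflux.pipeline import simulate_frap_nucleus


def make_curve(times, E, pre_index=0):
    return RecoveryCurve(
        nucleus_id=0, times_min=np.asarray(times, float),
        E=np.asarray(E, float), pre_ratio=0.4, pre_index=pre_index,
    )


class TestSumProjection:
    def test_two_unit_slices_sum_to_two(self):
        stack = np.ones((2, 4, 4))
        assert np.array_equal(sum_projection(stack), np.full((4, 4), 2.0))

    def test_linearity(self, rng):
        stack = rng.uniform(size=(6, 5, 5))
        assert np.allclose(sum_projection(3 * stack), 3 * sum_projection(stack))

    def test_half_stack_projection_uses_exact_range(self, rng):
        stack = rng.uniform(size=(8, 5, 5))
        top = sum_projection(stack, z_range=(4, 8))
        assert np.allclose(top, stack[4:8].sum(axis=0))

    def test_empty_range_raises(self):
        with pytest.raises(GeometryError):
            sum_projection(np.ones((4, 3, 3)), z_range=(2, 2))


class TestExtentOfRecoveryPipeline:
    def test_no_bleach_gives_unit_extent(self, mid_nucleus, imaging_clean):
        from sypflux.kinetics import state_from_nucleus, simulate_recovery, KineticParams
        from sypflux.render import render_series
        from sypflux.frap import extent_of_recovery
        from sypflux.geometry import corner_background_rois

        state = state_from_nucleus(mid_nucleus)
        geom = geometry_for_radius(mid_nucleus.radius_um, imaging_clean)
        pre = state.copy(); pre.time_min = -2.5
        states = [pre] + simulate_recovery(state, KineticParams(0.5, 0.1), [0.0, 5.0, 10.0])
        series = render_series(states, imaging_clean, geom)
        nx = geom.shape[2]
        roi_b = RectangleROI(x0=5, x1=nx // 2, y0=5, y1=geom.shape[1] - 5)
        roi_n = EllipseROI(cx=nx / 2, cy=nx / 2, rx=nx / 2 - 1, ry=nx / 2 - 1)
        curve = extent_of_recovery(
            series, roi_b, roi_n, pre_index=0,
            background_rois=corner_background_rois(geom.shape[1:], size=5),
        )
        assert np.allclose(curve.E, 1.0, atol=1e-6)

    def test_rendered_pipeline_matches_compartment_closed_form(
        self, mid_nucleus, imaging_clean
    ):
        rec = simulate_frap_nucleus(
            mid_nucleus, imaging_clean, np.random.default_rng(0),
            bleach_fraction=0.4,
        )
        curve = rec["curve"]
        post = curve.post_mask
        oracle = closed_form_extent(curve.times_min[post], rec["a"], 0.25, 0.5, 0.1)
        assert np.all(np.abs(curve.E[post] - oracle) / oracle < 0.02)
        assert curve.E[curve.pre_index] == pytest.approx(1.0)

    def test_fully_bleached_nucleus_has_degenerate_unit_extent(
        self, mid_nucleus, imaging_clean
    ):
        # bleached ROI == nucleus ROI: the ratio statistic is identically 1,
        # so absolute (reference-normalized) recovery must be used instead
        rec = simulate_frap_nucleus(
            mid_nucleus, imaging_clean, np.random.default_rng(0),
            bleach_fraction=0.999,
        )
        curve = rec["curve"]
        assert np.allclose(curve.E[curve.post_mask], 1.0, atol=0.05)


class TestPlateau:
    def test_constant_curve_same_under_both_rules(self):
        t = np.arange(-2.5, 31, 2.5)
        curve = make_curve(t, np.where(t < 0, 1.0, 0.6))
        assert plateau(curve) == pytest.approx(0.6)
        cfg = AnalysisConfig(plateau_rule="fit_asymptote")
        assert plateau(curve, cfg) == pytest.approx(0.6, abs=1e-6)

    def test_closed_form_curve_asymptote(self):
        t = np.arange(-2.5, 31, 2.5)
        E = np.where(t < 0, 1.0, closed_form_extent(np.clip(t, 0, None), 0.4, 0.25, 0.5, 0.1))
        curve = make_curve(t, E)
        cfg = AnalysisConfig(plateau_rule="fit_asymptote")
        assert plateau(curve, cfg) == pytest.approx(0.679, abs=2e-3)

    def test_mean_rule_below_asymptote_for_monotone_curve(self):
        t = np.arange(-2.5, 31, 2.5)
        E = np.where(t < 0, 1.0, closed_form_extent(np.clip(t, 0, None), 0.4, 0.25, 0.5, 0.1))
        curve = make_curve(t, E)
        assert plateau(curve) <= plateau(
            curve, AnalysisConfig(plateau_rule="fit_asymptote")
        ) + 1e-9

    def test_missing_late_points_raises_with_rule_name(self):
        curve = make_curve([-2.5, 0.0, 5.0], [1.0, 0.4, 0.5])
        with pytest.raises(ValueError, match="mean_after_25min"):
            plateau(curve)


class TestFitRecovery:
    def test_noise_free_parameters_recovered_exactly(self):
        t = np.arange(-2.5, 31, 2.5)
        E = np.where(t < 0, 1.0, 0.679 - (0.679 - 0.357) * np.exp(-0.1 * np.clip(t, 0, None)))
        fit = fit_recovery(make_curve(t, E))
        assert fit.E0 == pytest.approx(0.357, abs=1e-6)
        assert fit.E_inf == pytest.approx(0.679, abs=1e-6)
        assert fit.k_hat == pytest.approx(0.1, abs=1e-6)

    def test_mobile_fraction_closed_form_inversion(self):
        t = np.arange(-2.5, 31, 2.5)
        E = np.where(t < 0, 1.0, 0.679 - (0.679 - 0.357) * np.exp(-0.1 * np.clip(t, 0, None)))
        fit = fit_recovery(make_curve(t, E), bleach_fraction_a=0.4, survival_s=0.25)
        # f = (0.679*0.7 - 0.25)/(0.7 - 0.25)
        assert fit.f_hat == pytest.approx(0.5, abs=2e-3)
        assert not fit.clipped

    def test_flat_curve_gives_zero_rate(self):
        t = np.arange(-2.5, 31, 2.5)
        fit = fit_recovery(make_curve(t, np.where(t < 0, 1.0, 0.45)))
        assert fit.E_inf == pytest.approx(0.45, abs=1e-6)
        assert fit.k_hat == pytest.approx(0.0, abs=1e-3)


class TestPositionAndStage:
    @pytest.mark.parametrize(
        "row,n_rows,expected_x,expected_stage",
        [(6, 24, 0.25, "early"), (24, 24, 1.0, "late"), (12, 24, 0.5, "mid")],
    )
    def test_row_normalization_and_staging(self, row, n_rows, expected_x, expected_stage):
        x, stage = position_and_stage(row, n_rows)
        assert x == pytest.approx(expected_x)
        assert stage == expected_stage

    def test_out_of_range_row_raises(self):
        with pytest.raises(ValueError):
            position_and_stage(0, 24)


class TestStrongRecovery:
    def _series(self, bleached_value, unbleached_value, bg=10.0):
        imaging = ImagingParams(noise="none", background_level=bg)
        geom = geometry_for_radius(1.0, imaging)
        frame = np.full(geom.shape, bg)
        frame[:, :5, :] = bg + bleached_value
        frame[:, -5:, :] = bg + unbleached_value
        series = TimeSeriesStack(
            times_min=[30.0], frames=[{"syp": frame}], imaging=imaging, geometry=geom
        )
        m1 = np.zeros(geom.shape, bool); m1[:, :5, :] = True
        m2 = np.zeros(geom.shape, bool); m2[:, -5:, :] = True
        return series, m1, m2

    def test_ratio_above_tau_is_strong(self):
        series, m1, m2 = self._series(85.0, 100.0)
        assert strong_recovery_call(series, m1, m2, tau=0.8)

    def test_fresh_bleach_is_not_strong(self):
        series, m1, m2 = self._series(25.0, 100.0)
        assert not strong_recovery_call(series, m1, m2, tau=0.8)

    def test_fully_mobile_recovery_at_30min_is_strong(self):
        # kinetic oracle: f=1, k=0.1 -> ratio 1 - 0.75 e^(-3) ~ 0.96
        ratio = 1 - 0.75 * np.exp(-0.1 * 30)
        series, m1, m2 = self._series(100 * ratio, 100.0)
        assert strong_recovery_call(series, m1, m2, tau=0.8)

    def test_overlapping_masks_rejected(self):
        series, m1, _ = self._series(50.0, 100.0)
        with pytest.raises(ValueError):
            strong_recovery_call(series, m1, m1)


class TestReferenceNormalizedTotal:
    def _two_nucleus_series(self, bleach_factors):
        """Uniform 'nuclei' as two bright squares; the first is bleached by
        the given per-time factors, the reference stays constant."""
        imaging = ImagingParams(noise="none", background_level=5.0)
        geom = geometry_for_radius(2.0, imaging)
        frames = []
        for fct in bleach_factors:
            frame = np.full(geom.shape, 5.0)
            frame[:, 5:15, 5:15] += 100.0 * fct
            frame[:, 30:40, 30:40] += 100.0
            frames.append({"syp": frame})
        times = [-2.5 + 2.5 * i for i in range(len(bleach_factors))]
        series = TimeSeriesStack(
            times_min=times, frames=frames, imaging=imaging, geometry=geom
        )
        roi_n = RectangleROI(x0=5, x1=15, y0=5, y1=15)
        roi_r = RectangleROI(x0=30, x1=40, y0=30, y1=40)
        from sypflux.geometry import corner_background_rois

        return series, roi_n, roi_r, corner_background_rois(geom.shape[1:], size=4)

    def test_no_bleach_ratio_is_unity(self):
        series, roi_n, roi_r, bg = self._two_nucleus_series([1.0, 1.0, 1.0])
        ratios = reference_normalized_total(series, roi_n, roi_r, 0, bg)
        assert np.allclose(ratios, 1.0, atol=1e-9)

    def test_partial_bleach_drops_then_stays_constant(self):
        # survival 0.25 over content fraction 0.4 -> total factor 0.72
        series, roi_n, roi_r, bg = self._two_nucleus_series([1.0, 0.72, 0.72, 0.72])
        ratios = reference_normalized_total(series, roi_n, roi_r, 0, bg)
        assert ratios[1] == pytest.approx(0.72, abs=1e-9)
        assert np.allclose(ratios[1:], 0.72, atol=0.01 * 0.72)

    def test_full_bleach_flatlines_at_survival(self):
        series, roi_n, roi_r, bg = self._two_nucleus_series([1.0, 0.25, 0.25])
        ratios = reference_normalized_total(series, roi_n, roi_r, 0, bg)
        assert np.allclose(ratios[1:], 0.25, atol=1e-9)
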