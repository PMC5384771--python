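import numpy as np
import pytest

from sypflux.distribution import (
    assign_foci,
    classify_evenness,
    detect_foci,
    nucleus_mean_intensity,
    ramp_fit,
    trace_masks_from_truth,
    trace_mean_intensities,
    window_filter,
    x_association_tally,
)
from sypflux.kinetics import state_from_nucleus
from sypflux.render import ImagingParams, geometry_for_radius, render_state
from sypflux.synthetic import SCTrace


class TestNucleusMeanIntensity:
    def test_uniform_image_returns_value(self):
        img = np.full((40, 40), 3.0)
        mean, clipped = nucleus_mean_intensity(img, (20, 20), 10)
        assert mean == pytest.approx(3.0)
        assert not clipped

    def test_linearity_in_image_values(self, rng):
        img = rng.uniform(1, 5, (40, 40))
        m1, _ = nucleus_mean_intensity(img, (20, 20), 12)
        m2, _ = nucleus_mean_intensity(2 * img, (20, 20), 12)
        assert m2 == pytest.approx(2 * m1)

    def test_border_clipping_is_flagged(self):
        img = np.ones((40, 40))
        _, clipped = nucleus_mean_intensity(img, (3, 3), 10)
        assert clipped

    def test_rendered_density_doubling_doubles_mean(self, mid_nucleus, imaging_clean):
        geom = geometry_for_radius(mid_nucleus.radius_um, imaging_clean)
        state = state_from_nucleus(mid_nucleus)
        bg = imaging_clean.background_level * geom.shape[0]
        center = (geom.shape[1] / 2, geom.shape[2] / 2)
        r_px = mid_nucleus.radius_um / imaging_clean.voxel_xy_um
        means = []
        for scale in (1.0, 2.0):
            s = state.copy()
            s.B = state.B * scale
            proj = render_state(s, imaging_clean, geom)["syp"].sum(axis=0)
            m, _ = nucleus_mean_intensity(proj, center, r_px, background=bg)
            means.append(m)
        assert means[1] / means[0] == pytest.approx(2.0, rel=1e-3)


class TestRampFit:
    def test_flat_profile_fold_is_one(self):
        fit = ramp_fit([5.0, 5.0, 5.0, 5.0], [0.1, 0.4, 0.7, 1.0])
        assert fit.fold_change == pytest.approx(1.0)

    def test_exact_line_reproduces_fold_and_r2(self):
        x = np.linspace(0.05, 1.0, 12)
        y = 1.0 + 1.1 * x
        fit = ramp_fit(y, x)
        assert fit.fold_change == pytest.approx(2.1, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_narrow_position_span_rejected(self):
        with pytest.raises(ValueError):
            ramp_fit([1, 2, 3], [0.5, 0.55, 0.6])


class TestEvenness:
    def test_equal_intensities_are_even(self):
        call = classify_evenness([1, 1, 1, 1, 1, 1])
        assert call.classification == "even"
        assert call.evenness_ratio == pytest.approx(1.0)
        assert call.n_enriched == 0

    def test_single_enriched_trace_flagged(self):
        call = classify_evenness([2, 1, 1, 1, 1, 1], theta=1.5)
        assert call.classification == "uneven"
        assert call.evenness_ratio == pytest.approx(2.0)
        assert call.n_enriched == 1

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            classify_evenness([1, -0.1, 1])

    def test_truth_masks_reproduce_intensity_shares(self, mid_nucleus, imaging_clean):
        geom = geometry_for_radius(mid_nucleus.radius_um, imaging_clean)
        state = state_from_nucleus(mid_nucleus)
        frame = render_state(state, imaging_clean, geom)["syp"]
        masks = trace_masks_from_truth(mid_nucleus.traces, geom)
        I = trace_mean_intensities(
            frame, masks, background=imaging_clean.background_level
        )
        # equal-density traces: per-trace means should agree within bleed
        assert I.max() / np.median(I) < 1.5
        assert np.all(I > 0)


class TestWindowFilter:
    def test_boundary_x_excluded_from_second_half(self):
        assert window_filter([0.5], "second_half") == []

    def test_just_past_threshold_included_in_last_quarter(self):
        assert window_filter([0.76], "last_quarter") == [0.76]

    def test_uniform_rows_give_quarter_sized_window(self):
        xs = [(r + 1) / 24 for r in range(24)]
        assert len(window_filter(xs, "last_quarter")) == 6


class TestFocusDetection:
    def _planted_stack(self, positions, imaging, rng=None):
        geom = geometry_for_radius(2.0, imaging)
        trace = SCTrace(
            trace_id=0, chromosome_label="X",
            points=np.stack([np.linspace(-1.5, 1.5, 40), np.zeros(40), np.zeros(40)], 1),
            density=1.0,
        )
        from sypflux.kinetics import NucleusState
        from sypflux.render import render_state as rs

        state = NucleusState(
            points=trace.points, capacity=np.ones(40), B=np.ones(40),
            trace_index=np.zeros(40, int), radius_um=2.0,
            foci=[(np.asarray(p), 0) for p in positions],
        )
        return rs(state, imaging, geom, rng, channels=("foci",))["foci"], geom

    def test_zero_planted_foci_zero_detections(self, imaging_clean):
        stack, geom = self._planted_stack([], imaging_clean)
        assert detect_foci(stack, geom) == []

    def test_single_focus_found_within_one_voxel(self, imaging_noisy):
        pos = np.array([0.4, -0.3, 0.2])
        stack, geom = self._planted_stack([pos], imaging_noisy, np.random.default_rng(0))
        calls = detect_foci(stack, geom)
        assert len(calls) == 1
        err = np.abs(calls[0].position_um - pos)
        assert err[0] <= 0.1 and err[1] <= 0.1 and err[2] <= 0.24

    def test_detection_is_deterministic_given_stack(self, imaging_noisy):
        stack, geom = self._planted_stack(
            [np.array([0.0, 0.0, 0.0])], imaging_noisy, np.random.default_rng(3)
        )
        a = detect_foci(stack, geom)
        b = detect_foci(stack, geom)
        assert len(a) == len(b) == 1
        assert np.array_equal(a[0].position_um, b[0].position_um)


class TestAssignFoci:
    def _trace(self, tid, y):
        pts = np.stack([np.linspace(-1, 1, 21), np.full(21, y), np.zeros(21)], 1)
        return SCTrace(trace_id=tid, chromosome_label="I", points=pts, density=1.0)

    def test_focus_on_trace_assigned_at_zero_distance(self):
        from sypflux.distribution import FocusCall

        traces = [self._trace(0, 0.0), self._trace(1, 0.8)]
        f = FocusCall(position_um=np.array([0.0, 0.0, 0.0]), intensity=1.0)
        out = assign_foci([f], traces)
        assert out[0].trace_id == 0
        assert out[0].distance_um == pytest.approx(0.0)

    def test_distant_focus_stays_unassigned(self):
        from sypflux.distribution import FocusCall

        traces = [self._trace(0, 0.0)]
        f = FocusCall(position_um=np.array([0.0, 1.9, 0.0]), intensity=1.0)
        out = assign_foci([f], traces, d_max_um=0.3)
        assert out[0].trace_id is None

    def test_tie_breaks_to_lower_trace_id(self):
        from sypflux.distribution import FocusCall

        traces = [self._trace(1, 0.2), self._trace(0, -0.2)]
        f = FocusCall(position_um=np.array([0.0, 0.0, 0.0]), intensity=1.0)
        out = assign_foci([f], traces)
        assert out[0].trace_id == 0


class TestXAssociation:
    def test_empty_tally(self):
        assert x_association_tally([]) == (0, 0)

    def test_bookkeeping(self):
        k, n = x_association_tally(["X", "I", "X", "V", "II"])
        assert (k, n) == (2, 5)

    def test_uniform_assignment_matches_one_sixth(self, rng):
        labels = ["I", "II", "III", "IV", "V", "X"]
        picks = rng.choice(labels, size=600)
        k, n = x_association_tally(picks)
        p = 1 / 6
        assert abs(k / n - p) < 3 * np.sqrt(p * (1 - p) / n)
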