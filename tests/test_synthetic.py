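import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from sypflux.synthetic import (
    ConfigurationError,
    GonadSpec,
    GenotypeParams,
    apply_enrichment,
    assign_breaks,
    build_layout,
    occupancy_from_counts,
    sample_sc_traces,
    simulate_break_counts,
)
from sypflux.config import SCENARIOS


class TestTraceSampling:
    def test_containment_and_count(self, rng):
        traces = sample_sc_traces(2.0, 6, rng)
        assert len(traces) == 6
        for t in traces:
            assert np.all(np.linalg.norm(t.points, axis=1) <= 2.0)

    def test_single_trace_needs_no_separation(self, rng):
        traces = sample_sc_traces(1.5, 1, rng, total_length_range_um=(2.0, 8.0))
        assert len(traces) == 1

    def test_fixed_rng_reproduces_control_points(self):
        # three pairs: scale the karyotype-wide length budget down to match
        rng_kwargs = dict(total_length_range_um=(10.0, 14.0))
        a = sample_sc_traces(2.0, 3, np.random.default_rng(7), **rng_kwargs)
        b = sample_sc_traces(2.0, 3, np.random.default_rng(7), **rng_kwargs)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.points, tb.points)

    def test_pairwise_separation_respected(self, rng):
        traces = sample_sc_traces(2.0, 6, rng, min_separation_um=0.3)
        from scipy.spatial.distance import cdist

        zscale = np.array([1.0, 1.0, 0.5])
        for i in range(6):
            for j in range(i + 1, 6):
                d = cdist(traces[i].points * zscale, traces[j].points * zscale)
                assert d.min() >= 0.3

    def test_exactly_one_x_chromosome(self, rng):
        traces = sample_sc_traces(2.0, 6, rng)
        assert sum(t.chromosome_label == "X" for t in traces) == 1


class TestBuildLayout:
    def test_identical_seed_gives_identical_layouts(self, small_spec):
        g = SCENARIOS["wt"]
        a = build_layout(small_spec, g, 7)
        b = build_layout(small_spec, g, 7)
        for na, nb in zip(a.nuclei, b.nuclei):
            assert na.mobile_fraction_f == nb.mobile_fraction_f
            for ta, tb in zip(na.traces, nb.traces):
                assert np.array_equal(ta.points, tb.points)

    def test_stage_subset_matches_full_layout(self, small_spec):
        g = SCENARIOS["wt"]
        full = build_layout(small_spec, g, 7)
        late = build_layout(small_spec, g, 7, stages=("late",))
        full_late = full.nuclei_in_stage("late")
        assert [n.nucleus_id for n in late.nuclei] == [
            n.nucleus_id for n in full_late
        ]
        for na, nb in zip(late.nuclei, full_late):
            assert np.array_equal(na.traces[0].points, nb.traces[0].points)

    def test_flat_ramp_gives_equal_density(self):
        spec = GonadSpec(n_rows=4, nuclei_per_row=1, ramp_fold=1.0)
        layout = build_layout(spec, GenotypeParams(label="flat"), 1)
        densities = {n.base_density for n in layout.nuclei}
        assert len(densities) == 1

    def test_ramp_endpoint_densities(self):
        spec = GonadSpec(n_rows=10, nuclei_per_row=1, ramp_fold=2.1)
        layout = build_layout(spec, GenotypeParams(label="g"), 1)
        d0 = layout.nuclei[0].base_density
        d1 = layout.nuclei[-1].base_density
        assert d1 / d0 == pytest.approx(2.1)

    def test_stage_assignment_follows_boundaries(self, small_spec):
        layout = build_layout(small_spec, SCENARIOS["wt"], 3)
        for n in layout.nuclei:
            b1, b2 = small_spec.stage_boundaries
            expected = "early" if n.x <= b1 else ("mid" if n.x <= b2 else "late")
            assert n.stage == expected

    def test_invalid_spec_names_field(self):
        with pytest.raises(ConfigurationError, match="ramp_fold"):
            build_layout(
                dataclasses.replace(GonadSpec(), ramp_fold=-1.0),
                GenotypeParams(label="g"),
                1,
            )


class TestBreakAssignment:
    def test_zero_rate_gives_zero_foci(self, small_spec):
        g = GenotypeParams(label="none", break_rate_lambda=0.0)
        layout = build_layout(small_spec, g, 5)
        assign_breaks(layout, np.random.default_rng(0))
        assert all(n.n_foci == 0 for n in layout.nuclei)

    def test_wild_type_rule_one_focus_per_pair_in_late(self, small_spec):
        layout = build_layout(small_spec, SCENARIOS["wt"], 5)
        assign_breaks(layout, np.random.default_rng(0))
        for n in layout.nuclei:
            if n.stage == "late":
                assert n.n_foci == small_spec.n_pairs
                assert all(len(t.foci) == 1 for t in n.traces)
            else:
                assert n.n_foci == 0

    def test_zero_class_fraction_matches_poisson(self):
        # fraction with >= 1 focus should approach 1 - e^(-0.2)
        g = GenotypeParams(label="s", break_rate_lambda=0.2)
        counts = simulate_break_counts(g, 10_000, np.random.default_rng(11))
        frac = (counts >= 1).mean()
        expected = 1 - np.exp(-0.2)
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 10_000))

    def test_effective_counts_pass_poisson_gof(self):
        # thinning by h leaves a Poisson with mean lambda*(1-h)
        g = GenotypeParams(label="t", break_rate_lambda=1.0, heterosynapsis_fraction_h=0.4)
        counts = simulate_break_counts(g, 10_000, np.random.default_rng(5))
        lam = 1.0 * 0.6
        kmax = max(counts.max(), 5)
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = sps.poisson.pmf(np.arange(kmax + 1), lam) * len(counts)
        expected[-1] += (1 - sps.poisson.cdf(kmax, lam)) * len(counts)
        keep = expected > 5
        stat = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = sps.chi2.sf(stat, keep.sum() - 1)
        assert p > 0.01

    def test_occupancy_respects_cap(self, rng):
        occ = occupancy_from_counts(np.array([10, 0, 3]), 2, rng, max_per_trace=4)
        assert occ[0] == 2 and occ[1] == 0 and 1 <= occ[2] <= 2


class TestEnrichment:
    def _late_nucleus(self, seed=5):
        layout = build_layout(
            GonadSpec(n_rows=4, nuclei_per_row=1), SCENARIOS["wt"], seed,
            stages=("late",),
        )
        return layout, layout.nuclei[0]

    def test_no_foci_leaves_intensities_unchanged(self):
        layout, nuc = self._late_nucleus()
        before = [t.total_intensity for t in nuc.traces]
        apply_enrichment(layout)
        assert [t.total_intensity for t in nuc.traces] == before

    def test_single_focus_trace_takes_two_sevenths_share(self):
        layout, nuc = self._late_nucleus()
        # equalize trace lengths so shares depend on enrichment alone
        for t in nuc.traces:
            t.points = t.points * (4.0 / t.length_um)
        nuc.traces[2].foci = [1.0]
        total_before = nuc.total_trace_intensity
        apply_enrichment(layout)
        shares = [t.total_intensity / nuc.total_trace_intensity for t in nuc.traces]
        assert shares[2] == pytest.approx(2 / 7)
        assert nuc.total_trace_intensity == pytest.approx(total_before)

    def test_inactive_pathway_never_enriches(self):
        layout = build_layout(
            GonadSpec(n_rows=4, nuclei_per_row=1), SCENARIOS["plk2-dsb2"], 5,
            stages=("late",),
        )
        assign_breaks(layout, np.random.default_rng(1))
        assert any(n.n_foci > 0 for n in layout.nuclei)
        apply_enrichment(layout)
        for n in layout.nuclei:
            assert all(t.enrichment == 1.0 for t in n.traces)
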