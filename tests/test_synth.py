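"""Synthetic kymograph generator: determinism, recovery, rate simulations."""

import numpy as np
import pytest

from motilimap.classify import classify_event, event_features
from motilimap.detect import build_cell_matrix, label_events
from motilimap.io_masks import measure_diameters
from motilimap.stats import one_sample_t, pre_post_log2
from motilimap.synth import (
    GroundTruthEvent,
    SimulationSpec,
    baseline_profile,
    generate_length_trace,
    generate_masks,
    generate_matrix,
    ground_truth_to_contractions,
    sample_segment_counts,
    simulate_single_event,
)


class TestGenerateMatrix:
    def test_zero_events_zero_noise_is_baseline(self):
        spec = SimulationSpec(length_mm=20.0, n_frames=12, seed=0)
        dm, events = generate_matrix(spec)
        assert events == []
        assert np.allclose(dm.values, baseline_profile(spec)[:, None])
        assert len(label_events(build_cell_matrix(dm))) == 0

    def test_seeding_contract_bit_identical(self):
        spec = SimulationSpec(length_mm=20.0, n_frames=30, noise_sd_mm=0.05, seed=42)
        a, _ = generate_matrix(spec)
        b, _ = generate_matrix(spec)
        assert np.array_equal(a.values, b.values)

    def test_single_ripple_recovered_end_to_end(self):
        spec = SimulationSpec(length_mm=30.0, n_frames=80, seed=1)
        ev = GroundTruthEvent(
            type="ripple", onset_time_s=10.0, initiation_site_mm=10.0,
            velocity_mm_per_s=0.25, direction="anterograde", duration_s=20.0,
            amplitude_frac=0.3, halfwidth_mm=1.0, kernel="square", envelope="square",
        )
        dm, _ = generate_matrix(spec, [ev])
        detected = label_events(build_cell_matrix(dm))
        assert len(detected) == 1
        d = event_features(detected[0], spec.length_mm, dm=dm)
        assert classify_event(d) == "ripple"
        assert d.velocity_mm_per_s == pytest.approx(0.25, rel=0.05)
        assert d.direction == "anterograde"

    def test_overlapping_events_flagged(self):
        spec = SimulationSpec(length_mm=20.0, n_frames=30, seed=0)
        mk = lambda: GroundTruthEvent(
            type="standing", onset_time_s=5.0, initiation_site_mm=10.0,
            velocity_mm_per_s=0.0, direction="none", duration_s=10.0,
            amplitude_frac=0.3, halfwidth_mm=0.5, kernel="square", envelope="square",
        )
        with pytest.warns(UserWarning, match="overlap"):
            generate_matrix(spec, [mk(), mk()])

    def test_values_clipped_nonnegative(self):
        spec = SimulationSpec(length_mm=20.0, n_frames=40, noise_sd_mm=2.0, seed=9)
        dm, _ = generate_matrix(spec)
        assert np.nanmin(dm.values) >= 0.0


class TestGenerateMasks:
    def test_constant_profile_band_width(self):
        from motilimap.io_masks import DiameterMatrix

        dm = DiameterMatrix(np.full((4, 2), 2.0), dx_mm=0.5, dt_s=1.0)
        stack = generate_masks(dm, px_per_mm=10.0)
        widths = stack.frames[0].sum(axis=1)
        assert (widths == 20).all()

    def test_round_trip_within_one_pixel(self, rng):
        from motilimap.io_masks import DiameterMatrix

        vals = rng.uniform(0.8, 3.5, size=(20, 4))
        dm = DiameterMatrix(vals, dx_mm=0.5, dt_s=1.0)
        stack = generate_masks(dm, px_per_mm=10.0)
        back = measure_diameters(stack, roi_width_mm=0.5)
        assert np.nanmax(np.abs(back.values - vals)) <= 0.1

    def test_zero_diameter_rows_empty(self):
        from motilimap.io_masks import DiameterMatrix

        vals = np.full((4, 1), 2.0)
        vals[2, 0] = 0.0
        dm = DiameterMatrix(vals, dx_mm=0.5, dt_s=1.0)
        stack = generate_masks(dm, px_per_mm=10.0)
        assert not stack.frames[0, 10:15].any()

    def test_coarse_calibration_warns(self):
        from motilimap.io_masks import DiameterMatrix

        dm = DiameterMatrix(np.full((4, 1), 2.0), dx_mm=0.5, dt_s=1.0)
        with pytest.warns(UserWarning, match="coarse"):
            generate_masks(dm, px_per_mm=4.0)


class TestGenerateLengthTrace:
    def test_sustained_reduction_recovered(self):
        from motilimap.stats import length_reduction

        spec = SimulationSpec(length_mm=50.0, dt_s=1.0, n_frames=1200, seed=0)
        trace, _ = generate_length_trace(spec, sustained=(600.0, 0.2))
        out = length_reduction(trace, event_time_s=600.0)
        assert out["percent_reduction"] == pytest.approx(20.0)

    def test_no_events_flat(self):
        spec = SimulationSpec(length_mm=50.0, dt_s=1.0, n_frames=100, seed=0)
        trace, _ = generate_length_trace(spec)
        assert np.allclose(trace.length_mm, 50.0)


class TestSingleEventRecovery:
    """Noise-free single-event experiments: the generator's ground truth is
    recovered by the full detect+classify chain."""

    @pytest.mark.parametrize("etype", ["standing", "ripple", "slow"])
    def test_one_event_per_type(self, etype):
        rng = np.random.default_rng({"standing": 11, "ripple": 22, "slow": 33}[etype])
        dm, gt, spec = simulate_single_event(rng, etype)
        detected = label_events(build_cell_matrix(dm))
        assert len(detected) == 1
        ev = event_features(detected[0], spec.length_mm, dm=dm)
        assert classify_event(ev) == etype
        assert ev.amplitude_pct == pytest.approx(100 * gt.amplitude_frac, rel=0.10)
        if etype != "standing":
            gt_slope, _ = gt.path_regression(spec.dt_s)
            assert ev.velocity_mm_per_s == pytest.approx(abs(gt_slope), rel=0.05)
            assert ev.direction == gt.direction

    def test_wave_orthogonal_to_drift(self):
        gt = GroundTruthEvent(
            type="slow", onset_time_s=0.0, initiation_site_mm=20.0,
            velocity_mm_per_s=0.1, direction="anterograde", duration_s=60.0,
            amplitude_frac=0.3, halfwidth_mm=2.0, kernel="square",
            envelope="square", wave_amp_mm=3.0, wave_cycles=2,
        )
        slope, r2 = gt.path_regression(dt_s=1 / 1.2)
        assert slope == pytest.approx(0.1, abs=1e-9)
        assert r2 < 0.8


class TestRateSimulation:
    """Poisson rate model behind the pre/post statistical experiments."""

    def test_counts_scale_with_rates(self, rng):
        lengths = np.array([23.4, 13.8, 13.8, 9.0])
        rates = np.array([0.108, 0.198, 0.144, 0.043])
        counts = np.stack(
            [sample_segment_counts(rng, rates, 10.0, lengths) for _ in range(400)]
        )
        lam = rates * 10.0 * lengths
        assert np.allclose(counts.mean(axis=0), lam, rtol=0.15)

    def test_injected_hindgut_effect_detected(self, rng):
        """Doubling the hindgut rate yields a significantly positive log2
        ratio over 12 replicates; halving the foregut rate a negative one."""
        lengths = np.array([23.4, 13.8, 13.8, 9.0])
        before_rates = np.array([0.108, 0.198, 0.144, 0.043])
        after_rates = before_rates * np.array([0.5, 0.5, 1.0, 2.0])
        hits_s1 = hits_s4 = 0
        n_meta = 100
        for _ in range(n_meta):
            b = np.stack(
                [sample_segment_counts(rng, before_rates, 10.0, lengths) for _ in range(12)]
            )
            a = np.stack(
                [sample_segment_counts(rng, after_rates, 10.0, lengths) for _ in range(12)]
            )
            cpm_b = b / (10.0 * lengths)
            cpm_a = a / (10.0 * lengths)
            r1, _ = pre_post_log2(cpm_b[:, 0], cpm_a[:, 0])
            r4, _ = pre_post_log2(cpm_b[:, 3], cpm_a[:, 3])
            t1 = one_sample_t(r1)
            t4 = one_sample_t(r4)
            hits_s1 += t1.tier == "**" and t1.mean < 0
            hits_s4 += t4.tier == "**" and t4.mean > 0
        assert hits_s1 / n_meta >= 0.8
        assert hits_s4 / n_meta >= 0.8

    def test_ground_truth_to_contractions_summary(self, rng):
        gts = [
            GroundTruthEvent(
                type="ripple", onset_time_s=float(10 * i), initiation_site_mm=55.0,
                velocity_mm_per_s=0.3, direction="anterograde", duration_s=10.0,
                amplitude_frac=0.2, halfwidth_mm=1.0,
            )
            for i in range(5)
        ]
        events = ground_truth_to_contractions(gts, total_length_mm=60.0)
        from motilimap.classify import summarize

        s = summarize(events, (0, 60), 60.0)
        assert int(s.counts.loc[4, "ripple"]) == 5
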