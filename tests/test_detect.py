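"""Local-minima extraction, similar-diameter extension, and event labeling."""

from collections import deque

import numpy as np
import pytest

from motilimap.detect import (
    ContractionCellMatrix,
    build_cell_matrix,
    cell_amplitude,
    extend_minima,
    filter_events,
    find_local_minima,
    label_events,
)
from motilimap.classify import classify_event, event_features
from motilimap.io_masks import DiameterMatrix
from motilimap.synth import SimulationSpec, generate_matrix


def _dm(values, dx=0.5, dt=1.0):
    return DiameterMatrix(np.asarray(values, float), dx_mm=dx, dt_s=dt)


class TestFindLocalMinima:
    @pytest.mark.parametrize(
        "profile,threshold,expected",
        [
            ([5, 5, 3, 5, 5], 1.0, [2]),  # obvious minimum
            ([5, 5, 5, 5], 1.0, []),  # flat profile: no contraction
            ([5, 4.5, 5], 1.0, []),  # depth 0.5 below the threshold
            ([8, 3, 8], 1.0, [1]),  # sharp isolated dip
            ([8, 3, 3, 3, 8], 1.0, [1, 2, 3]),  # plateau returned in full
            ([9, 2, 5, 3, 8], 1.0, [1, 3]),  # two dips, inner flank at 5
        ],
    )
    def test_worked_profiles(self, profile, threshold, expected):
        got = find_local_minima(np.array(profile, float), threshold)
        assert got.tolist() == expected

    def test_short_profile_empty(self):
        assert find_local_minima(np.array([5.0, 3.0]), 1.0).size == 0

    def test_nan_splits_profile(self):
        profile = np.array([8, 3, 8, np.nan, 8, 2, 8], float)
        assert find_local_minima(profile, 1.0).tolist() == [1, 5]


class TestExtendMinima:
    def test_similar_diameter_neighbours_join(self):
        # a minimum at 3 with neighbours 3.5 and 3 within tolerance 1:
        # three cells form the contraction
        profile = np.array([8, 8, 3, 3.5, 3, 8, 8], float)
        minima = find_local_minima(profile, 1.0)
        cells = extend_minima(profile, minima, 1.0)
        assert cells.tolist() == [2, 3, 4]

    def test_isolated_minimum_stays_single(self):
        profile = np.array([8, 3, 8], float)
        assert extend_minima(profile, np.array([1]), 1.0).tolist() == [1]

    def test_zero_tolerance_joins_only_exact_equals(self):
        profile = np.array([8, 3, 3, 3.5, 8], float)
        cells = extend_minima(profile, np.array([1, 2]), 0.0)
        assert cells.tolist() == [1, 2]

    def test_empty_minima_empty_cells(self):
        assert extend_minima(np.array([1.0, 2, 3]), np.array([], int), 1.0).size == 0


class TestCellAmplitude:
    def test_symmetric_dip(self):
        assert cell_amplitude(np.array([8, 8, 3, 8, 8], float), np.array([2])) == 5.0

    def test_lower_flank_convention(self):
        assert cell_amplitude(np.array([6, 3, 8], float), np.array([1])) == 3.0

    def test_nearest_flank_convention(self):
        # left local max 9 is one step away, right max 8 is two steps away:
        # 'nearest' uses 9, 'lower' uses 8
        profile = np.array([4, 3, 9, 2, 8, 8, 1], float)
        assert cell_amplitude(profile, np.array([3]), flank="nearest") == 7.0
        assert cell_amplitude(profile, np.array([3]), flank="lower") == 6.0

    def test_edge_run_uses_single_flank(self):
        # run at the oral edge: only the anal-side flank (rising to 8) exists
        assert cell_amplitude(np.array([3, 5, 8], float), np.array([0])) == 5.0


class TestBuildCellMatrix:
    def test_constant_matrix_no_cells(self):
        cm = build_cell_matrix(_dm(np.full((10, 5), 2.0)))
        assert np.isnan(cm.amplitude).all()

    def test_single_frame_notch(self):
        vals = np.full((10, 5), 2.0)
        vals[4, 2] = 1.0
        cm = build_cell_matrix(_dm(vals), depth_threshold=0.5)
        cells = np.argwhere(np.isfinite(cm.amplitude))
        assert cells.tolist() == [[4, 2]]
        assert cm.amplitude[4, 2] == pytest.approx(1.0)

    def test_one_dip_per_frame(self):
        vals = np.full((12, 6), 2.0)
        for t in range(6):
            vals[3 + t, t] = 1.2
        cm = build_cell_matrix(_dm(vals))
        assert np.isfinite(cm.amplitude).sum() == 6

    def test_translation_equivariance(self, rng):
        vals = np.full((15, 8), 2.5) + rng.normal(0, 0.02, size=(15, 8))
        vals[5:8, 3] -= 1.0
        a = build_cell_matrix(_dm(vals))
        b = build_cell_matrix(_dm(vals + 3.0))
        assert np.array_equal(
            np.isfinite(a.amplitude), np.isfinite(b.amplitude)
        )
        assert np.allclose(a.amplitude, b.amplitude, equal_nan=True)


def _flood_fill_components(mask, connectivity=8):
    """Brute-force BFS component count/labeling oracle."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    rows, cols = mask.shape
    for i in range(rows):
        for j in range(cols):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                q = deque([(i, j)])
                seen[i, j] = True
                while q:
                    a, b = q.popleft()
                    comp.add((a, b))
                    for da, db in nbrs:
                        x, y = a + da, b + db
                        if 0 <= x < rows and 0 <= y < cols and mask[x, y] and not seen[x, y]:
                            seen[x, y] = True
                            q.append((x, y))
                comps.append(comp)
    return comps


def _cm_from_mask(mask):
    amp = np.where(mask, 1.0, np.nan)
    return ContractionCellMatrix(
        amp, dx_mm=0.5, dt_s=1.0, total_length_mm=mask.shape[0] * 0.5,
        depth_threshold=0.1, similarity_tol=0.1,
    )


class TestLabelEvents:
    def test_two_separated_clusters(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        events = label_events(_cm_from_mask(mask))
        assert len(events) == 2

    def test_diagonal_chain_connectivity_contract(self):
        mask = np.eye(6, dtype=bool)
        assert len(label_events(_cm_from_mask(mask), connectivity=8)) == 1
        assert len(label_events(_cm_from_mask(mask), connectivity=4)) == 6

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(60):
            mask = rng.random((rng.integers(3, 20), rng.integers(3, 20))) < 0.3
            events = label_events(_cm_from_mask(mask), connectivity=connectivity)
            oracle = _flood_fill_components(mask, connectivity)
            assert len(events) == len(oracle)
            got = sorted(
                sorted(zip(ev.pos_idx.tolist(), ev.t_idx.tolist())) for ev in events
            )
            want = sorted(sorted(c) for c in oracle)
            assert got == want

    def test_partition_covers_cells_once(self, rng):
        mask = rng.random((20, 20)) < 0.35
        events = label_events(_cm_from_mask(mask))
        covered = set()
        for ev in events:
            for cell in zip(ev.pos_idx.tolist(), ev.t_idx.tolist()):
                assert cell not in covered
                covered.add(cell)
        assert len(covered) == int(mask.sum())


class TestFilterEvents:
    def _typed_events(self, amps_pct):
        mask = np.zeros((20, len(amps_pct) * 2), bool)
        for i in range(len(amps_pct)):
            mask[5, 2 * i] = True
        events = label_events(_cm_from_mask(mask))
        for ev, a in zip(events, amps_pct):
            ev.amplitude_pct = a
            ev.duration_s = 0.0
        return events

    def test_amplitude_floor(self):
        events = self._typed_events([4.9, 5.1, 60.0])
        kept = filter_events(events, min_amplitude_frac=0.05)
        assert [ev.amplitude_pct for ev in kept] == [5.1, 60.0]

    def test_zero_floor_is_identity(self):
        events = self._typed_events([1.0, 2.0])
        assert filter_events(events, min_amplitude_frac=0.0) == events

    def test_ground_truth_count_above_floor(self, rng):
        amps = rng.uniform(1, 20, size=12).tolist()
        events = self._typed_events(amps)
        kept = filter_events(events, min_amplitude_frac=0.05)
        assert len(kept) == sum(a >= 5.0 for a in amps)


def test_noise_free_injected_events_all_recovered(small_recording):
    """Well-separated injected events map 1:1 onto detected events."""
    dm, gts, spec = small_recording
    cm = build_cell_matrix(dm)
    events = label_events(cm)
    assert len(events) == len(gts)
    for ev in events:
        event_features(ev, spec.length_mm, dm=dm)
        classify_event(ev)
    assert sorted(ev.type for ev in events) == sorted(gt.type for gt in gts)
    # each detected footprint overlaps exactly one ground-truth site
    for ev in events:
        matches = [
            gt
            for gt in gts
            if abs(ev.initiation_site_mm - gt.initiation_site_mm) < 3.0
            and abs(ev.time_s.min() - gt.onset_time_s) < 3.0
        ]
        assert len(matches) == 1


def test_small_noise_does_not_change_event_count():
    spec = SimulationSpec(length_mm=30.0, n_frames=120, noise_sd_mm=0.01, seed=5)
    from motilimap.synth import GroundTruthEvent

    events = [
        GroundTruthEvent(
            type="standing", onset_time_s=30.0, initiation_site_mm=15.0,
            velocity_mm_per_s=0.0, direction="none", duration_s=10.0,
            amplitude_frac=0.4, halfwidth_mm=0.25, kernel="square", envelope="square",
        )
    ]
    dm, _ = generate_matrix(spec, events)
    detected = label_events(build_cell_matrix(dm))
    assert len(detected) == 1
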