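"""Scanpath event layer: fixation detection, AOI assignment, run segmentation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gazesearch as gs
from gazesearch.events import AOI_H, AOI_W, CENTER_CELL, nominal_center

from conftest import brute_force_runs, fixations_from_labels, make_layout

PX_PER_DEG = 200.0 / 4.4  # grid pitch of 200 px spans 4.4 deg


# ---------------------------------------------------------------------------
# detect_fixations
# ---------------------------------------------------------------------------


class TestDetectFixations:
    def test_stationary_gaze_is_one_fixation(self):
        t = np.arange(0, 500.0)
        fx = gs.detect_fixations(t, np.full(500, 300.0), np.full(500, 400.0),
                                 sampling_rate=1000, px_per_deg=PX_PER_DEG)
        assert len(fx) == 1
        assert fx[0].duration == 500
        assert fx[0].x == pytest.approx(300.0)

    def test_fast_sweep_splits_two_fixations(self):
        # 300 deg/s sweep for 20 ms between two 200-ms stationary epochs
        t = np.arange(0, 420.0)
        x = np.concatenate([
            np.full(200, 100.0),
            100.0 + 300.0 * PX_PER_DEG / 1000 * np.arange(1, 21),
            np.full(200, 100.0 + 300.0 * PX_PER_DEG / 1000 * 20),
        ])
        fx = gs.detect_fixations(t, x, np.full(420, 0.0),
                                 sampling_rate=1000, px_per_deg=PX_PER_DEG)
        assert len(fx) == 2
        assert abs(fx[0].duration - 200) <= 1
        assert abs(fx[1].duration - 200) <= 1

    def test_roundtrip_recovers_simulated_run_sequence(self):
        """Rendered sample stream from a known run sequence: recovered count
        and durations within one sample period of the generating events."""
        layout = make_layout([0, 2, 4, 8, 13])
        truth = fixations_from_labels([0, 2, 1, 4, 3], [180, 220, 150, 310, 240],
                                      layout, gap_ms=40)
        t, x, y = gs.render_samples(truth, sampling_rate=1000)
        fx = gs.detect_fixations(t, x, y, sampling_rate=1000,
                                 px_per_deg=PX_PER_DEG)
        assert len(fx) == len(truth)
        for got, want in zip(fx, truth):
            assert abs(got.duration - want.duration) <= 1
            assert abs(got.onset - want.onset) <= 1
            assert np.hypot(got.x - want.x, got.y - want.y) < 1.0

    def test_input_contract_errors(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            gs.detect_fixations(np.array([0.0, 1.0]), np.zeros(2), np.zeros(2),
                                1000, PX_PER_DEG)
        t = np.array([0.0, 2.0, 1.0, 3.0])
        with pytest.raises(ValueError, match="increasing"):
            gs.detect_fixations(t, np.zeros(4), np.zeros(4), 1000, PX_PER_DEG)


# ---------------------------------------------------------------------------
# assign_aoi
# ---------------------------------------------------------------------------


class TestAssignAoi:
    def test_containment_at_stimulus_center(self):
        layout = make_layout([3, 9])
        gi, cx, cy = layout.cells[0]
        fix = gs.FixationEvent(onset=0, duration=100, x=cx, y=cy)
        assert gs.assign_aoi(fix, layout).aoi_id == gi

    def test_outside_rect_goes_to_nearest_center(self):
        # 60 px right of a stimulus center: outside its 50.5-px half width,
        # but far closer than any other AOI center (>= 140 px away)
        layout = make_layout([3, 9])
        gi, cx, cy = layout.cells[0]
        fix = gs.FixationEvent(onset=0, duration=100, x=cx + 60, y=cy)
        assert gs.assign_aoi(fix, layout).aoi_id == gi

    def test_midway_tie_breaks_to_lower_grid_index(self):
        # exactly midway between the centers of cells 0 and 1 (no jitter),
        # below both rectangles so containment cannot decide
        layout = make_layout([0, 1])
        (g0, x0, y0), (g1, x1, _) = layout.cells
        fix = gs.FixationEvent(onset=0, duration=100, x=(x0 + x1) / 2,
                               y=y0 + AOI_H / 2 + 1)
        assert gs.assign_aoi(fix, layout).aoi_id == min(g0, g1)

    @given(x=st.floats(0, 1920), y=st.floats(0, 1080))
    def test_assignment_is_total_and_deterministic(self, x, y):
        layout = make_layout([0, 5, 16], jitter=[(10, -5), (0, 0), (-10, 5)])
        fix = gs.FixationEvent(onset=0, duration=10, x=x, y=y)
        a = gs.assign_aoi(fix, layout)
        assert a.aoi_id in range(21)
        assert gs.assign_aoi(fix, layout).aoi_id == a.aoi_id

    @given(cell=st.integers(0, 20), dx=st.floats(-50.5, 50.5),
           dy=st.floats(-65, 65))
    def test_containment_agrees_with_nearest_center(self, cell, dx, dy):
        """Inside a rectangle, containment and nearest-center coincide
        (centers are >= 180 px apart by the display geometry)."""
        occupied = [cell] if cell != CENTER_CELL else [cell - 1]
        layout = make_layout(occupied)
        gi, cx, cy = layout.cells[0]
        fix = gs.FixationEvent(onset=0, duration=10, x=cx + dx, y=cy + dy)
        got = gs.assign_aoi(fix, layout).aoi_id
        centers = layout.full_grid_centers()
        nearest = int(np.argmin(np.sum((centers - [fix.x, fix.y]) ** 2, axis=1)))
        assert got == gi == nearest

    def test_batch_matches_scalar(self, rng):
        layout = make_layout([2, 7, 12], jitter=[(5, 5), (-10, 0), (0, 10)])
        fixs = [gs.FixationEvent(onset=i, duration=10,
                                 x=float(rng.uniform(0, 1920)),
                                 y=float(rng.uniform(0, 1080)))
                for i in range(200)]
        batch = gs.assign_aoi_batch(fixs, layout)
        for f, b in zip(fixs, batch):
            assert gs.assign_aoi(f, layout).aoi_id == b.aoi_id


# ---------------------------------------------------------------------------
# drop_unoccupied
# ---------------------------------------------------------------------------


class TestDropUnoccupied:
    def test_occupied_only_is_identity_with_labels(self):
        layout = make_layout([0, 2])
        fixs = [gs.FixationEvent(0, 100, 0, 0, aoi_id=0),
                gs.FixationEvent(100, 80, 0, 0, aoi_id=2)]
        out = gs.drop_unoccupied(fixs, layout)
        assert [(f.onset, f.stimulus_id) for f in out] == [(0, 0), (100, 1)]

    def test_empty_cell_fixations_removed_order_kept(self):
        layout = make_layout([0, 2])
        aois = [0, 5, 2, 10, 0, 7, 2, 2, 5, 0]  # cells 5, 7, 10 unoccupied
        fixs = [gs.FixationEvent(10 * i, 10, 0, 0, aoi_id=a)
                for i, a in enumerate(aois)]
        out = gs.drop_unoccupied(fixs, layout)
        assert len(out) == 6
        assert [f.onset for f in out] == sorted(f.onset for f in out)

    def test_all_on_empty_cells_yields_empty(self):
        layout = make_layout([0, 2])
        fixs = [gs.FixationEvent(0, 100, 0, 0, aoi_id=10)]
        assert gs.drop_unoccupied(fixs, layout) == []


# ---------------------------------------------------------------------------
# segment_runs
# ---------------------------------------------------------------------------


class TestSegmentRuns:
    def test_worked_example(self):
        layout = make_layout([0, 2, 4, 8])
        fixs = fixations_from_labels([3, 3, 1, 3, 2], [150, 100, 200, 120, 180],
                                     make_layout([0, 2, 4, 8, 13]))
        runs = gs.segment_runs(fixs)
        got = [(r.stimulus_id, r.gaze_ms, r.is_revisit) for r in runs]
        assert got == [(3, 250, False), (1, 200, False), (3, 120, True),
                       (2, 180, False)]

    def test_single_fixation_and_uninterrupted_repeat(self):
        layout = make_layout([0, 2])
        one = gs.segment_runs(fixations_from_labels([1], [90], layout))
        assert len(one) == 1 and not one[0].is_revisit
        rep = gs.segment_runs(fixations_from_labels([1, 1, 1], [50, 60, 70], layout))
        assert len(rep) == 1
        assert rep[0].gaze_ms == 180
        assert not rep[0].is_revisit

    def test_empty_input(self):
        assert gs.segment_runs([]) == []

    @given(labels=st.lists(st.integers(0, 4), min_size=1, max_size=12))
    def test_matches_brute_force_scanner(self, labels):
        layout = make_layout([0, 1, 2, 3, 4])
        fixs = fixations_from_labels(labels, [100] * len(labels), layout)
        runs = gs.segment_runs(fixs)
        want = brute_force_runs(labels)
        assert [(r.stimulus_id, r.is_revisit) for r in runs] == [
            (w["stimulus"], w["is_revisit"]) for w in want
        ]
        # concatenating the runs reproduces the input exactly
        flat = [f for r in runs for f in r.fixations]
        assert flat == fixs
        # no two consecutive runs share a stimulus
        assert all(a.stimulus_id != b.stimulus_id for a, b in zip(runs, runs[1:]))
        # a revisit always has an intervening different-stimulus run
        for k, r in enumerate(runs):
            if r.is_revisit:
                prev = max(j for j in range(k) if runs[j].stimulus_id == r.stimulus_id)
                assert any(runs[j].stimulus_id != r.stimulus_id
                           for j in range(prev + 1, k))


class TestTruncateAtResponse:
    def test_clip_and_drop(self):
        fixs = [gs.FixationEvent(0, 100, 0, 0), gs.FixationEvent(150, 100, 0, 0),
                gs.FixationEvent(300, 100, 0, 0)]
        out = gs.truncate_at_response(fixs, 200)
        assert [(f.onset, f.duration) for f in out] == [(0, 100), (150, 50)]
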