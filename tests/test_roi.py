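"""RoI construction from scan streams and dynamic-exclusion weights."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddasim.roi import (DewConfig, Ms1Point, Roi, RoiBuilder, RoiParams,
                        exclusion_weight, update_rois)
from conftest import make_roi


def pts(rt, *mz_int):
    return [Ms1Point(mz, rt, i) for mz, i in mz_int]


class TestUpdateRois:
    def test_within_tolerance_extends(self):
        params = RoiParams(mz_tol=10.0, min_intensity=0.0)
        b = RoiBuilder(params)
        b.process_scan(pts(0.0, (100.0000, 1e4)))
        b.process_scan(pts(1.0, (100.0005, 1e4)))   # 5 ppm away
        assert len(b.live) == 1
        assert b.live[0].n_points == 2

    def test_outside_tolerance_seeds_new(self):
        params = RoiParams(mz_tol=10.0, min_intensity=0.0)
        b = RoiBuilder(params)
        b.process_scan(pts(0.0, (100.00, 1e4)))
        b.process_scan(pts(1.0, (100.01, 1e4)))     # 100 ppm away
        assert len(b.live) == 2

    def test_absolute_da_tolerance(self):
        params = RoiParams(mz_tol=0.02, mz_tol_unit="da", min_intensity=0.0)
        b = RoiBuilder(params)
        b.process_scan(pts(0.0, (100.00, 1e4)))
        b.process_scan(pts(1.0, (100.01, 1e4)))
        assert len(b.live) == 1

    def test_closure_after_max_missed(self):
        params = RoiParams(min_intensity=0.0, max_missed=2)
        b = RoiBuilder(params)
        b.process_scan(pts(0.0, (100.0, 1e4)))
        for k in range(1, 3):
            closed = b.process_scan([])
            assert closed == []
        closed = b.process_scan([])     # third consecutive miss
        assert len(closed) == 1
        assert closed[0].status == "closed"
        assert b.live == []

    def test_below_threshold_ignored(self):
        params = RoiParams(min_intensity=5000.0)
        b = RoiBuilder(params)
        b.process_scan(pts(0.0, (100.0, 100.0)))
        assert b.live == []

    def test_unsorted_scan_rejected(self):
        params = RoiParams(min_intensity=0.0)
        with pytest.raises(ValueError):
            update_rois([], pts(0.0, (200.0, 1.0), (100.0, 1.0)), params, 0)

    def test_tie_goes_to_nearest_then_lower_mz(self):
        params = RoiParams(mz_tol=0.5, mz_tol_unit="da", min_intensity=0.0)
        b = RoiBuilder(params)
        b.process_scan(pts(0.0, (100.0, 1e4), (100.4, 1e4)))
        assert len(b.live) == 2
        # 100.2 is equidistant from both RoIs — the lower-m/z RoI wins
        b.process_scan(pts(1.0, (100.2, 1e4)))
        by_mz = sorted(b.live, key=lambda r: r.mzs[0])
        assert by_mz[0].n_points == 2
        assert by_mz[1].n_points == 1

    def test_each_point_joins_exactly_one_roi(self):
        """Two points in one scan cannot both extend the same RoI."""
        params = RoiParams(mz_tol=0.5, mz_tol_unit="da", min_intensity=0.0)
        b = RoiBuilder(params)
        b.process_scan(pts(0.0, (100.0, 1e4)))
        b.process_scan(pts(1.0, (99.9, 1e4), (100.1, 1e4)))
        # nearer point (0.1 from either side: 99.9 first in mz order) extends,
        # the other seeds a new RoI
        assert sorted(r.n_points for r in b.live) == [1, 2]
        assert sum(r.n_points for r in b.all_rois) == 3

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_separated_traces_yield_one_roi_each(self, seed):
        """k well-separated m/z traces produce exactly k RoIs, and every
        point above threshold lands in exactly one of them."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 8))
        mzs = 100.0 + 10.0 * np.arange(k)
        n_scans = int(rng.integers(2, 10))
        b = RoiBuilder(RoiParams(min_intensity=0.0))
        for s in range(n_scans):
            b.process_scan(pts(float(s), *((m, 1e4) for m in mzs)))
        assert len(b.all_rois) == k
        assert all(r.n_points == n_scans for r in b.all_rois)

    def test_replay_is_deterministic(self):
        rng = np.random.default_rng(7)
        scans = []
        for s in range(20):
            mzs = np.sort(rng.uniform(100, 110, 15))
            scans.append(pts(float(s), *((m, 1e4) for m in mzs)))

        def run():
            b = RoiBuilder(RoiParams(mz_tol=50.0, min_intensity=0.0))
            for scan in scans:
                b.process_scan(scan)
            b.close_all()
            return [(r.mzs, r.rts) for r in sorted(b.all_rois,
                                                   key=lambda r: r.id)]

        assert run() == run()


class TestExclusionWeight:
    def test_never_fragmented_is_one(self):
        roi = make_roi([0.0], [100.0], [1e4])
        for scheme in ("plain", "weighteddew", "smartroi"):
            assert exclusion_weight(roi, 5.0, DewConfig(scheme=scheme)) == 1.0

    def test_plain_hard_window(self):
        roi = make_roi([0.0], [100.0], [1e4])
        roi.record_fragmentation(0.0, 1e4)
        cfg = DewConfig(scheme="plain", rt_tol=15.0)
        assert exclusion_weight(roi, 7.5, cfg) == 0.0
        assert exclusion_weight(roi, 15.0, cfg) == 0.0   # closed boundary
        assert exclusion_weight(roi, 15.1, cfg) == 1.0

    def test_weighteddew_ramp_midpoint(self):
        roi = make_roi([0.0], [100.0], [1e4])
        roi.record_fragmentation(0.0, 1e4)
        cfg = DewConfig(scheme="weighteddew", rt_tol=11.0, t0=1.0)
        assert exclusion_weight(roi, 6.0, cfg) == pytest.approx(0.5)
        assert exclusion_weight(roi, 0.5, cfg) == 0.0
        assert exclusion_weight(roi, 11.0, cfg) == 1.0

    @pytest.mark.parametrize("scheme", ["plain", "weighteddew"])
    def test_monotone_in_elapsed_time(self, scheme):
        roi = make_roi([0.0], [100.0], [1e4])
        roi.record_fragmentation(0.0, 1e4)
        cfg = DewConfig(scheme=scheme, rt_tol=15.0, t0=3.0)
        ws = [exclusion_weight(roi, t, cfg) for t in np.linspace(0, 20, 81)]
        assert all(b >= a for a, b in zip(ws, ws[1:]))

    def test_smartroi_reenables_on_intensity_increase(self):
        cfg = DewConfig(scheme="smartroi", intensity_increase_factor=5.0,
                        drop_fraction=0.01, reset_length=1000.0)
        roi = make_roi([0.0], [100.0], [1e4])
        roi.record_fragmentation(0.0, 1e4)
        roi.add_point(Ms1Point(100.0, 1.0, 2e3))    # min since frag = 2e3
        assert exclusion_weight(roi, 1.0, cfg) == 0.0
        roi.add_point(Ms1Point(100.0, 2.0, 1.1e4))  # >= 5 x 2e3
        assert exclusion_weight(roi, 2.0, cfg) == 1.0

    def test_smartroi_reenables_on_drop(self):
        cfg = DewConfig(scheme="smartroi", intensity_increase_factor=100.0,
                        drop_fraction=0.1, reset_length=1000.0)
        roi = make_roi([0.0], [100.0], [1e5])
        roi.record_fragmentation(0.0, 1e5)
        roi.add_point(Ms1Point(100.0, 1.0, 5e3))    # < 0.1 x 1e5
        assert exclusion_weight(roi, 1.0, cfg) == 1.0

    def test_smartroi_reenables_after_timeout(self):
        cfg = DewConfig(scheme="smartroi", intensity_increase_factor=100.0,
                        drop_fraction=0.001, reset_length=30.0)
        roi = make_roi([0.0], [100.0], [1e5])
        roi.record_fragmentation(0.0, 1e5)
        roi.add_point(Ms1Point(100.0, 1.0, 9e4))
        assert exclusion_weight(roi, 1.0, cfg) == 0.0
        assert exclusion_weight(roi, 31.0, cfg) == 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DewConfig(t0=20.0, rt_tol=10.0)
        with pytest.raises(ValueError):
            DewConfig(drop_fraction=0.0)


class TestRoiState:
    def test_bounds_cover_all_points(self):
        roi = make_roi([0.0, 1.0, 2.0], [100.0, 100.001, 99.999],
                       [1e3, 1e4, 5e3])
        b = roi.bounds
        assert b.rt_lo == 0.0 and b.rt_hi == 2.0
        assert b.mz_lo == 99.999 and b.mz_hi == 100.001

    def test_current_intensity_tracks_latest_point(self):
        roi = make_roi([0.0, 1.0], [100.0, 100.0], [1e3, 7e3])
        assert roi.current_intensity == 7e3

    def test_max_frag_intensity(self):
        roi = make_roi([0.0], [100.0], [1e4])
        roi.record_fragmentation(0.0, 1e4)
        roi.record_fragmentation(10.0, 1e5)
        assert roi.max_frag_intensity == 1e5

    def test_non_increasing_rt_rejected(self):
        roi = make_roi([0.0], [100.0], [1e4])
        with pytest.raises(ValueError):
            roi.add_point(Ms1Point(100.0, 0.0, 1e4))
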