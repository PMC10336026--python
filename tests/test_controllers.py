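"""Scoring strategies: worked values, gates, reductions, scheduling rules."""

import math

import pytest

from ddasim.controllers import (Controller, ControllerConfig, ScanRequest,
                                STRATEGIES, on_ms2_performed,
                                schedule_duty_cycle, score)
from ddasim.exclusion import ExclusionRegistry, ExclusionWindow
from ddasim.geometry import Rect
from ddasim.roi import Ms1Point
from conftest import make_roi


def cfg_for(strategy, **kw):
    kw.setdefault("min_intensity", 5000.0)
    return ControllerConfig(strategy=strategy, **kw)


def carried(reg, rect, intensity):
    reg.carried.add(ExclusionWindow(rect, intensity, 0, "roi_box"))


class TestScoreValues:
    def test_topn_log_intensity(self):
        reg = ExclusionRegistry()
        p = Ms1Point(150.0, 10.0, 1e6)
        assert score(p, reg, cfg_for("topn"), 10.0) == pytest.approx(
            math.log(1e6), abs=1e-9)

    @pytest.mark.parametrize("strategy", ["topn", "topn_exclusion"])
    def test_min_intensity_gate(self, strategy):
        reg = ExclusionRegistry()
        p = Ms1Point(150.0, 10.0, 4999.0)
        assert score(p, reg, cfg_for(strategy), 10.0) == 0.0

    def test_roi_min_intensity_gate(self):
        reg = ExclusionRegistry()
        roi = make_roi([10.0], [150.0], [4999.0])
        for strategy in STRATEGIES[2:]:
            assert score(roi, reg, cfg_for(strategy), 10.0) == 0.0

    def test_excluded_precursor_scores_zero(self):
        reg = ExclusionRegistry()
        reg.register_fragmentation(150.0, 9.0, 1e6, mode="dew_box",
                                   mz_tol=0.01, rt_tol=15.0)
        p = Ms1Point(150.0, 10.0, 1e6)
        assert score(p, reg, cfg_for("topn"), 10.0) == 0.0

    def test_intensity_roi_exclusion_log_difference(self):
        reg = ExclusionRegistry()
        roi = make_roi([10.0], [150.0], [1e6])
        carried(reg, Rect(0, 20, 149.9, 150.1), 1e4)
        got = score(roi, reg, cfg_for("intensity_roi_exclusion"), 10.0)
        assert got == pytest.approx(math.log(1e6) - math.log(1e4), abs=1e-9)

    def test_intensity_roi_exclusion_clamped_at_zero(self):
        reg = ExclusionRegistry()
        roi = make_roi([10.0], [150.0], [1e6])
        carried(reg, Rect(0, 20, 149.9, 150.1), 1e7)
        assert score(roi, reg, cfg_for("intensity_roi_exclusion"), 10.0) == 0.0

    def test_non_overlap_weighted_log(self):
        """A RoI whose box is three-quarters uncovered scores
        0.75 * ln(intensity)."""
        reg = ExclusionRegistry()
        # rt span [0,2] padded by 0 -> use explicit pads of zero
        cfg = cfg_for("non_overlap", min_intensity=0.0,
                      roi_box_rt_pad=0.0, roi_box_mz_pad=0.0)
        roi = make_roi([0.0, 2.0], [10.0, 12.0], [1000.0, 1000.0])
        carried(reg, Rect(1.0, 3.0, 11.0, 13.0), 100.0)
        got = score(roi, reg, cfg, 2.0)
        assert got == pytest.approx(0.75 * math.log(1000.0), abs=1e-9)

    def test_intensity_non_overlap_worked_example(self):
        """ln(1000^0.75 + 900^0.25), the worked region enumeration."""
        reg = ExclusionRegistry()
        cfg = cfg_for("intensity_non_overlap", min_intensity=0.0,
                      roi_box_rt_pad=0.0, roi_box_mz_pad=0.0)
        roi = make_roi([0.0, 2.0], [10.0, 12.0], [1000.0, 1000.0])
        carried(reg, Rect(1.0, 3.0, 11.0, 13.0), 100.0)
        expected = math.log(1000.0 ** 0.75 + 900.0 ** 0.25)
        assert score(roi, reg, cfg, 2.0) == pytest.approx(expected, abs=1e-9)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            ControllerConfig(strategy="nope")


class TestReductions:
    def test_empty_state_non_overlap_equals_topn_roi(self):
        """With no exclusion state, prop = 1 and all plain-log strategies
        coincide at ln(intensity)."""
        reg = ExclusionRegistry()
        roi = make_roi([10.0], [150.0], [1e6])
        now = 10.0
        expected = math.log(1e6)
        for strategy in ("topn_roi", "non_overlap", "hard_roi_exclusion",
                         "intensity_roi_exclusion", "intensity_non_overlap"):
            assert score(roi, reg, cfg_for(strategy), now) == pytest.approx(
                expected, abs=1e-9), strategy

    def test_phi_sentinel_matches_topn_roi(self):
        """Never-fragmented RoIs score identically under topn_roi and
        intensity_roi_exclusion."""
        reg = ExclusionRegistry()
        carried(reg, Rect(0, 5, 100.0, 100.1), 1e6)   # elsewhere in m/z
        roi = make_roi([10.0], [150.0], [2e5])
        a = score(roi, reg, cfg_for("topn_roi"), 10.0)
        b = score(roi, reg, cfg_for("intensity_roi_exclusion"), 10.0)
        assert a == b == pytest.approx(math.log(2e5))

    def test_monotone_in_intensity(self):
        """Holding exclusion state fixed, higher current intensity never
        lowers any strategy's score."""
        reg = ExclusionRegistry()
        carried(reg, Rect(0, 20, 149.99, 150.01), 5e4)
        for strategy in STRATEGIES[2:]:
            cfg = cfg_for(strategy)
            prev = -1.0
            for lam in (1e4, 5e4, 1e5, 1e6, 1e7):
                roi = make_roi([10.0], [150.0], [lam])
                s = score(roi, reg, cfg, 10.0)
                assert s >= prev - 1e-12, strategy
                prev = s

    def test_dominating_carried_box_blocks_hard_and_intensity(self):
        """A candidate fully covered by a carried box at >= its intensity
        scores 0 under hard, intensity-exclusion and intensity-area
        strategies."""
        reg = ExclusionRegistry()
        carried(reg, Rect(0, 20, 149.9, 150.1), 1e6)
        roi = make_roi([9.0, 10.0], [150.0, 150.0], [1e6, 1e6])
        for strategy in ("hard_roi_exclusion", "intensity_roi_exclusion",
                         "intensity_non_overlap"):
            assert score(roi, reg, cfg_for(strategy), 10.0) == 0.0, strategy


class TestSchedule:
    def points(self, *mz_int, rt=10.0):
        return [Ms1Point(mz, rt, i) for mz, i in mz_int]

    def test_top_n_by_intensity(self):
        reg = ExclusionRegistry()
        cfg = cfg_for("topn", n=3)
        pts = self.points((100, 1e6), (110, 2e6), (120, 3e6),
                          (130, 4e6), (140, 5e6))
        reqs = schedule_duty_cycle(pts, [], reg, cfg, 10.0)
        assert [r.precursor_mz for r in reqs] == [140, 130, 120]
        assert all(r.precursor_intensity >= cfg.min_intensity for r in reqs)

    def test_all_excluded_yields_no_requests(self):
        reg = ExclusionRegistry()
        for mz in (100.0, 110.0):
            reg.register_fragmentation(mz, 9.0, 1e6, mode="dew_box",
                                       mz_tol=0.01, rt_tol=15.0)
        cfg = cfg_for("topn", n=5)
        reqs = schedule_duty_cycle(self.points((100, 1e6), (110, 2e6)),
                                   [], reg, cfg, 10.0)
        assert reqs == []

    def test_score_tie_breaks_to_lower_mz(self):
        reg = ExclusionRegistry()
        cfg = cfg_for("topn", n=1)
        reqs = schedule_duty_cycle(self.points((140, 1e6), (100, 1e6)),
                                   [], reg, cfg, 10.0)
        assert reqs[0].precursor_mz == 100

    def test_never_more_than_n(self):
        reg = ExclusionRegistry()
        cfg = cfg_for("topn", n=2)
        pts = self.points(*((100 + k, 1e6) for k in range(10)))
        assert len(schedule_duty_cycle(pts, [], reg, cfg, 10.0)) == 2

    def test_zero_score_requests_rejected(self):
        with pytest.raises(ValueError):
            ScanRequest(100.0, 1e6, 0.7, score=0.0)


class TestMs2Feedback:
    def test_topn_registers_dew(self):
        cfg = cfg_for("topn")
        reg = ExclusionRegistry()
        req = ScanRequest(150.0, 1e6, 0.7, score=1.0)
        on_ms2_performed(req, reg, cfg, rt=10.0, precursor_intensity=9e5)
        assert len(reg.within.windows) == 1
        assert reg.within.windows[0].intensity == 9e5

    def test_hard_roi_queues_carried_box(self):
        cfg = cfg_for("hard_roi_exclusion")
        reg = ExclusionRegistry()
        roi = make_roi([10.0], [150.0], [1e6])
        req = ScanRequest(150.0, 1e6, 0.7, score=1.0, target_roi=roi)
        on_ms2_performed(req, reg, cfg, rt=10.2, precursor_intensity=9e5)
        assert roi.frag_events == [(10.2, 9e5)]
        reg.end_injection()
        assert len(reg.carried.windows) == 1
        assert reg.carried.windows[0].intensity == 9e5

    def test_iterative_roi_variant_records_dew_geometry(self):
        cfg = cfg_for("topn_exclusion_roi")
        reg = ExclusionRegistry()
        roi = make_roi([10.0], [150.0], [1e6])
        req = ScanRequest(150.0, 1e6, 0.7, score=1.0, target_roi=roi)
        on_ms2_performed(req, reg, cfg, rt=10.2, precursor_intensity=9e5)
        assert len(reg.within.windows) == 1
        reg.end_injection(carry_dews=True)
        assert reg.carried.windows[0].kind == "dew"

    def test_controller_rollover_carries_per_strategy(self):
        for strategy, expect_kind in (("topn", None),
                                      ("topn_exclusion", "dew"),
                                      ("hard_roi_exclusion", "roi_box")):
            c = Controller(cfg_for(strategy))
            roi = make_roi([10.0], [150.0], [1e6])
            req = ScanRequest(150.0, 1e6, 0.7, score=1.0,
                              target_roi=roi if strategy != "topn_exclusion"
                              and strategy != "topn" else None)
            c.ms2_performed(req, 10.2, 9e5)
            c.end_injection()
            kinds = [w.kind for w in c.registry.carried.windows]
            assert kinds == ([] if expect_kind is None else [expect_kind]), strategy
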