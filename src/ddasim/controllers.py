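"""Scan-prioritization strategies and duty-cycle scheduling.

Every strategy scores candidates from the latest MS1 survey scan as

    score = w_ex * I(lambda >= lambda_min) * core

where ``w_ex`` is the exclusion term (a 0/1 indicator, or the SmartRoI /
WeightedDEW weight substituted in its place for RoI strategies) and
``core`` is the strategy-specific modified log intensity:

===================== ==========================================================
strategy              core and exclusion semantics
===================== ==========================================================
topn                  ln(lambda); within-injection DEW boxes only
topn_exclusion        ln(lambda); DEW boxes carried across injections
topn_roi              ln(lambda); RoI-tied DEW, no carryover
topn_exclusion_roi    ln(lambda); RoI-tied DEW + carried DEW-box geometry
hard_roi_exclusion    ln(lambda); RoI-tied DEW + hard exclusion by carried RoI
                      boxes
intensity_roi_exclusion  max(0, ln(lambda) - ln(phi)); phi = max intensity of
                      containing carried RoI boxes
non_overlap           prop * ln(lambda); prop = uncovered fraction of the RoI's
                      box against carried RoI boxes
intensity_non_overlap ln(sum_B max(0, lambda_B^prop_B)), clamped at 0; region
                      sum over the dissection against carried RoI boxes
===================== ==========================================================

The top-N positive-scoring candidates of each duty cycle become MS2 scan
requests; candidates at score 0 are never scheduled, so a duty cycle may
end with fewer than N MS2 scans.  Natural logarithms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .exclusion import ExclusionRegistry
from .geometry import Rect, dissect, intensity_region_sum, non_overlap_proportion
from .roi import DewConfig, Ms1Point, Roi, RoiBuilder, RoiParams, exclusion_weight

Strategy = Literal[
    "topn", "topn_exclusion", "topn_roi", "topn_exclusion_roi",
    "hard_roi_exclusion", "intensity_roi_exclusion",
    "non_overlap", "intensity_non_overlap",
]

STRATEGIES: tuple[str, ...] = (
    "topn", "topn_exclusion", "topn_roi", "topn_exclusion_roi",
    "hard_roi_exclusion", "intensity_roi_exclusion",
    "non_overlap", "intensity_non_overlap",
)

#: strategies whose candidates are live RoIs rather than raw MS1 peaks
ROI_STRATEGIES = frozenset(STRATEGIES[2:])
#: strategies that promote within-injection DEW boxes at rollover
CARRY_DEWS = frozenset({"topn_exclusion", "topn_exclusion_roi"})
#: strategies that carry fragmented-RoI bounding boxes across injections
CARRY_ROI_BOXES = frozenset({
    "hard_roi_exclusion", "intensity_roi_exclusion",
    "non_overlap", "intensity_non_overlap",
})


@dataclass
class ControllerConfig:
    strategy: Strategy = "topn"
    n: int = 10                       # max MS2 scans per duty cycle
    min_intensity: float = 5000.0     # lambda_min
    isolation_width: float = 0.7      # m/z
    dew: DewConfig = field(default_factory=DewConfig)
    roi: RoiParams = field(default_factory=RoiParams)
    dew_mz_tol: float = 0.01          # Da half-width of DEW boxes
    # symmetric padding applied when an RoI trace is treated as a box —
    # both the query RoI and carried fragmentation boxes.  An RoI's box
    # is physically its m/z tolerance band around the trace, not the bare
    # observed extent (which is degenerate for a noiseless trace); the rt
    # pad is about one duty cycle, the sampling resolution of the trace.
    roi_box_rt_pad: float = 1.0       # seconds
    roi_box_mz_pad: float = 0.01      # Da

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")


@dataclass(frozen=True)
class ScanRequest:
    precursor_mz: float
    precursor_intensity: float
    isolation_width: float
    score: float
    target_roi: Roi | None = None

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("scheduled requests must have positive score")


def score(candidate: Ms1Point | Roi, registry: ExclusionRegistry,
          cfg: ControllerConfig, now: float) -> float:
    """Score one candidate under the configured strategy.

    ``candidate`` is a raw MS1 peak for topn/topn_exclusion and a live
    RoI for the RoI strategies; its intensity is taken from the most
    recent MS1 scan.
    """
    strategy = cfg.strategy
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy: {strategy!r}")

    if isinstance(candidate, Roi):
        if strategy not in ROI_STRATEGIES:
            raise TypeError(f"{strategy} scores raw precursors, not RoIs")
        lam = candidate.current_intensity
        mz, rt = candidate.last_mz, candidate.last_rt
    else:
        if strategy in ROI_STRATEGIES:
            raise TypeError(f"{strategy} scores RoIs, not raw precursors")
        lam = candidate.intensity
        mz, rt = candidate.mz, candidate.rt

    if lam < cfg.min_intensity or lam <= 0:
        return 0.0

    if strategy in ("topn", "topn_exclusion"):
        excluded = registry.is_excluded(mz, rt, within=True,
                                        carried=(strategy == "topn_exclusion"))
        return 0.0 if excluded else math.log(lam)

    roi: Roi = candidate
    w = exclusion_weight(roi, now, cfg.dew)
    if w == 0.0:
        return 0.0

    if strategy in ("topn_exclusion_roi", "hard_roi_exclusion"):
        # last precursor contained in any carried window => hard exclusion
        if registry.is_excluded(mz, rt, within=False, carried=True):
            return 0.0
        return w * math.log(lam)
    if strategy == "topn_roi":
        return w * math.log(lam)
    if strategy == "intensity_roi_exclusion":
        phi = registry.phi(mz, rt)
        log_phi = math.log(phi) if phi is not None and phi > 0 else 0.0
        return w * max(0.0, math.log(lam) - log_phi)

    # area-weighted strategies: dissect the RoI's current bounding box
    # against carried-over fragmentation boxes
    b = roi.bounds
    bounds = Rect(b.rt_lo - cfg.roi_box_rt_pad, b.rt_hi + cfg.roi_box_rt_pad,
                  b.mz_lo - cfg.roi_box_mz_pad, b.mz_hi + cfg.roi_box_mz_pad)
    boxes = registry.carried_overlapping(bounds)
    d = dissect(bounds, [(i, b.rect) for i, b in enumerate(boxes)])
    if strategy == "non_overlap":
        return w * non_overlap_proportion(d) * math.log(lam)
    # intensity_non_overlap
    region_sum = intensity_region_sum(
        d, lam, {i: b.intensity for i, b in enumerate(boxes)})
    if region_sum <= 1.0:
        return 0.0
    return w * math.log(region_sum)


def schedule_duty_cycle(ms1_points: Sequence[Ms1Point], live_rois: Sequence[Roi],
                        registry: ExclusionRegistry, cfg: ControllerConfig,
                        now: float) -> list[ScanRequest]:
    """Rank this duty cycle's candidates and emit up to N scan requests.

    Candidates are the MS1 peaks themselves for non-RoI strategies, and
    the live RoIs that received a point in this scan for RoI strategies.
    Ordering: descending score, then descending raw intensity, then
    ascending m/z.  Zero-scored candidates are never scheduled.
    """
    scored: list[tuple[float, float, float, Ms1Point | Roi]] = []
    if cfg.strategy in ROI_STRATEGIES:
        for roi in live_rois:
            if roi.last_rt == now and roi.current_intensity >= cfg.min_intensity:
                s = score(roi, registry, cfg, now)
                if s > 0:
                    scored.append((s, roi.current_intensity, roi.last_mz, roi))
    else:
        for p in ms1_points:
            if p.intensity >= cfg.min_intensity:
                s = score(p, registry, cfg, now)
                if s > 0:
                    scored.append((s, p.intensity, p.mz, p))

    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    requests = []
    for s, lam, mz, cand in scored[:cfg.n]:
        requests.append(ScanRequest(
            precursor_mz=mz, precursor_intensity=lam,
            isolation_width=cfg.isolation_width, score=s,
            target_roi=cand if isinstance(cand, Roi) else None))
    return requests


def on_ms2_performed(request: ScanRequest, registry: ExclusionRegistry,
                     cfg: ControllerConfig, rt: float,
                     precursor_intensity: float) -> None:
    """Fold an executed MS2 scan back into exclusion and RoI state.

    Appends a fragmentation event to the target RoI (if any); registers
    the within-injection DEW appropriate to the strategy; and queues the
    RoI box / DEW geometry that the strategy carries across injections.
    """
    strategy = cfg.strategy
    roi = request.target_roi
    if roi is not None:
        roi.record_fragmentation(rt, precursor_intensity)

    if strategy in ROI_STRATEGIES:
        # within-injection exclusion is RoI-tied (exclusion_weight); the
        # iterative-exclusion variant additionally records the DEW-box
        # geometry that a non-RoI method would have produced, for carryover
        if strategy == "topn_exclusion_roi":
            registry.register_fragmentation(
                request.precursor_mz, rt, precursor_intensity,
                mode="dew_box", mz_tol=cfg.dew_mz_tol, rt_tol=cfg.dew.rt_tol)
        if strategy in CARRY_ROI_BOXES and roi is not None:
            registry.register_fragmentation(
                request.precursor_mz, rt, precursor_intensity,
                mode="roi_box", roi=roi)
    else:
        registry.register_fragmentation(
            request.precursor_mz, rt, precursor_intensity,
            mode="dew_box", mz_tol=cfg.dew_mz_tol, rt_tol=cfg.dew.rt_tol)


class Controller:
    """Stateful acquisition controller threading scoring across injections."""

    def __init__(self, cfg: ControllerConfig):
        self.cfg = cfg
        self.registry = ExclusionRegistry()
        self.roi_builder = RoiBuilder(cfg.roi)

    def begin_injection(self) -> None:
        """Reset per-injection state; carried-over windows persist."""
        self.roi_builder = RoiBuilder(self.cfg.roi)

    def process_ms1(self, points: Sequence[Ms1Point], now: float) -> list[ScanRequest]:
        if self.cfg.strategy in ROI_STRATEGIES:
            self.roi_builder.process_scan(points)
        return schedule_duty_cycle(points, self.roi_builder.live,
                                   self.registry, self.cfg, now)

    def ms2_performed(self, request: ScanRequest, rt: float,
                      precursor_intensity: float) -> None:
        on_ms2_performed(request, self.registry, self.cfg, rt, precursor_intensity)

    def end_injection(self) -> None:
        self.registry.end_injection(
            carry_dews=self.cfg.strategy in CARRY_DEWS,
            rt_pad=self.cfg.roi_box_rt_pad, mz_pad=self.cfg.roi_box_mz_pad)
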