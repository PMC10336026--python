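"""Real-time Region-of-Interest tracking and dynamic exclusion weights.

A Region of Interest (RoI) is a trace of MS1 points grouped across
retention time within an m/z tolerance — the real-time stand-in for a
chromatographic peak.  Construction follows the centwave point-linking
rule: each point of an incoming MS1 scan either extends the nearest live
RoI within tolerance or seeds a new one, and a RoI that goes unmatched
for more than ``max_missed`` consecutive scans is closed.

The same module houses the within-injection dynamic-exclusion weight of
a RoI: ``plain`` (hard 0/1 window of ``rt_tol`` seconds after the last
fragmentation), ``weighteddew`` (linear ramp from 0 back to 1 between
``t0`` and ``rt_tol``), and ``smartroi`` (re-enable on a sufficient
intensity rise, on decay of the peak, or after a timeout).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Literal, Sequence

from .geometry import Rect


@dataclass(frozen=True)
class Ms1Point:
    mz: float
    rt: float
    intensity: float


@dataclass
class DewConfig:
    """Within-injection dynamic exclusion behaviour of a fragmented RoI.

    rt_tol is the exclusion duration in seconds.  For weighteddew the
    weight ramps linearly from 0 at ``t0`` seconds after fragmentation to
    1 at ``rt_tol``.  For smartroi the RoI is re-enabled when its current
    intensity reaches ``intensity_increase_factor`` times the minimum
    seen since fragmentation, when it drops below ``drop_fraction`` times
    the intensity at fragmentation, or ``reset_length`` seconds after the
    event, whichever comes first.
    """

    scheme: Literal["plain", "smartroi", "weighteddew"] = "plain"
    rt_tol: float = 15.0
    t0: float = 3.0
    intensity_increase_factor: float = 10.0
    drop_fraction: float = 0.1
    reset_length: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.t0 <= self.rt_tol):
            raise ValueError("require 0 <= t0 <= rt_tol")
        if self.intensity_increase_factor < 1.0:
            raise ValueError("intensity_increase_factor must be >= 1")
        if not (0.0 < self.drop_fraction <= 1.0):
            raise ValueError("drop_fraction must be in (0, 1]")


class Roi:
    """A live or closed trace of MS1 points with fragmentation history."""

    __slots__ = ("id", "mzs", "rts", "intensities", "frag_events", "status",
                 "missed", "_min_since_frag", "_intensity_at_frag")

    def __init__(self, roi_id: int, point: Ms1Point):
        self.id = roi_id
        self.mzs = [point.mz]
        self.rts = [point.rt]
        self.intensities = [point.intensity]
        self.frag_events: list[tuple[float, float]] = []  # (rt, precursor intensity)
        self.status = "live"
        self.missed = 0
        self._min_since_frag = math.inf
        self._intensity_at_frag = 0.0

    # --- point stream -------------------------------------------------
    def add_point(self, point: Ms1Point) -> None:
        if point.rt <= self.rts[-1]:
            raise ValueError("RoI points must be strictly increasing in rt")
        self.mzs.append(point.mz)
        self.rts.append(point.rt)
        self.intensities.append(point.intensity)
        self.missed = 0
        if self.frag_events:
            self._min_since_frag = min(self._min_since_frag, point.intensity)

    def miss(self, max_missed: int) -> bool:
        """Record a scan with no matching point; True if the RoI closes."""
        self.missed += 1
        if self.missed > max_missed:
            self.status = "closed"
            return True
        return False

    # --- views --------------------------------------------------------
    @property
    def last_mz(self) -> float:
        return self.mzs[-1]

    @property
    def last_rt(self) -> float:
        return self.rts[-1]

    @property
    def current_intensity(self) -> float:
        """lambda_r: intensity in the most recent MS1 scan that hit this RoI."""
        return self.intensities[-1]

    @property
    def n_points(self) -> int:
        return len(self.rts)

    @property
    def bounds(self) -> Rect:
        """Bounding box at query time (grows to the right as points arrive)."""
        return Rect(self.rts[0], self.rts[-1], min(self.mzs), max(self.mzs))

    @property
    def last_frag_rt(self) -> float | None:
        return self.frag_events[-1][0] if self.frag_events else None

    @property
    def max_frag_intensity(self) -> float:
        """Highest precursor intensity over this RoI's fragmentation events."""
        return max((i for _, i in self.frag_events), default=0.0)

    # --- fragmentation ------------------------------------------------
    def record_fragmentation(self, rt: float, precursor_intensity: float) -> None:
        self.frag_events.append((rt, precursor_intensity))
        self._intensity_at_frag = precursor_intensity
        self._min_since_frag = math.inf

    def smartroi_enabled(self, now: float, cfg: DewConfig) -> bool:
        if not self.frag_events:
            return True
        if now - self.frag_events[-1][0] >= cfg.reset_length:
            return True
        lam = self.current_intensity
        if self._min_since_frag < math.inf and \
                lam >= cfg.intensity_increase_factor * self._min_since_frag:
            return True
        if lam < cfg.drop_fraction * self._intensity_at_frag:
            return True
        return False


def exclusion_weight(roi: Roi, now: float, cfg: DewConfig) -> float:
    """Exclusion weight of a RoI in [0, 1] under the configured DEW scheme.

    A never-fragmented RoI always weighs 1.  Substituted in place of the
    0/1 exclusion indicator in every RoI-based scoring strategy.
    """
    if not roi.frag_events:
        return 1.0
    dt = now - roi.frag_events[-1][0]
    if dt < 0:
        raise ValueError("query time precedes last fragmentation")
    if cfg.scheme == "plain":
        return 1.0 if dt > cfg.rt_tol else 0.0
    if cfg.scheme == "weighteddew":
        if dt >= cfg.rt_tol:
            return 1.0
        if dt < cfg.t0:
            return 0.0
        return (dt - cfg.t0) / (cfg.rt_tol - cfg.t0)
    if cfg.scheme == "smartroi":
        return 1.0 if roi.smartroi_enabled(now, cfg) else 0.0
    raise ValueError(f"unknown DEW scheme: {cfg.scheme!r}")


@dataclass
class RoiParams:
    """centwave-style RoI construction parameters.

    mz_tol is interpreted in ppm of the RoI's last point by default, or
    as an absolute Da half-width when ``mz_tol_unit`` is ``"da"``.
    min_intensity gates both seeding and extension; max_missed is the
    number of consecutive empty scans tolerated before a RoI closes.
    """

    mz_tol: float = 10.0
    mz_tol_unit: Literal["ppm", "da"] = "ppm"
    min_intensity: float = 5000.0
    max_missed: int = 3

    def tol_da(self, mz: float) -> float:
        return self.mz_tol * 1e-6 * mz if self.mz_tol_unit == "ppm" else self.mz_tol


def update_rois(
    live_rois: list[Roi],
    scan_points: Sequence[Ms1Point],
    params: RoiParams,
    next_id: int,
) -> tuple[list[Roi], list[Roi], int]:
    """Advance all live RoIs by one MS1 scan.

    Each scan point at or above the intensity threshold extends the live
    RoI whose last m/z is nearest within tolerance (ties to the lower-m/z
    RoI), at most one point per RoI per scan; otherwise it seeds a new
    RoI.  RoIs unmatched for more than max_missed scans are closed.

    Returns (live, newly_closed, next_id).  Scan points must be sorted
    by m/z.
    """
    mzs = [p.mz for p in scan_points]
    if any(b < a for a, b in zip(mzs, mzs[1:])):
        raise ValueError("scan points must be sorted by m/z")

    taken: set[int] = set()      # indices into live_rois already extended
    new_rois: list[Roi] = []
    order = sorted(range(len(live_rois)), key=lambda i: live_rois[i].last_mz)
    order_mz = [live_rois[i].last_mz for i in order]

    for p in scan_points:
        if p.intensity < params.min_intensity:
            continue
        # nearest untaken live RoI by last-point m/z, via outward scan from
        # the insertion point in the sorted order; ties go to the lower m/z
        pos = bisect.bisect_left(order_mz, p.mz)
        best_i = -1
        best_d = math.inf
        li, ri = pos - 1, pos
        while li >= 0:
            d = p.mz - order_mz[li]
            tol = params.tol_da(order_mz[li])
            if best_d <= d or d > max(tol, params.tol_da(p.mz)):
                break
            i = order[li]
            if i not in taken and d <= tol:
                best_i, best_d = i, d
                break
            li -= 1
        while ri < len(order):
            d = order_mz[ri] - p.mz
            tol = params.tol_da(order_mz[ri])
            # <= on best_d: exact-distance ties keep the lower-m/z match
            if best_d <= d or d > tol:
                break
            i = order[ri]
            if i not in taken and d <= tol:
                best_i, best_d = i, d
                break
            ri += 1
        if best_i >= 0:
            live_rois[best_i].add_point(p)
            taken.add(best_i)
        else:
            roi = Roi(next_id, p)
            next_id += 1
            new_rois.append(roi)

    live: list[Roi] = []
    newly_closed: list[Roi] = []
    for i, r in enumerate(live_rois):
        if i in taken:
            live.append(r)
        elif r.miss(params.max_missed):
            newly_closed.append(r)
        else:
            live.append(r)
    live.extend(new_rois)
    return live, newly_closed, next_id


class RoiBuilder:
    """Stateful wrapper threading :func:`update_rois` over a scan stream."""

    def __init__(self, params: RoiParams | None = None):
        self.params = params or RoiParams()
        self.live: list[Roi] = []
        self.closed: list[Roi] = []
        self._next_id = 0

    def process_scan(self, points: Sequence[Ms1Point]) -> list[Roi]:
        """Consume one MS1 scan; returns the RoIs newly closed by it."""
        self.live, newly_closed, self._next_id = update_rois(
            self.live, points, self.params, self._next_id)
        self.closed.extend(newly_closed)
        return newly_closed

    def close_all(self) -> None:
        for r in self.live:
            r.status = "closed"
        self.closed.extend(self.live)
        self.live = []

    @property
    def all_rois(self) -> list[Roi]:
        return self.closed + self.live
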