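"""Exclusion-window registry with within- and between-injection lifetimes.

Two populations of windows are kept separate because the scoring
strategies consult them differently:

* *within-injection* dynamic exclusion windows (DEWs) — a box around each
  fragmentation event spanning ``[rt, rt + rt_tol]`` in retention time;
  cleared (or promoted, for iterative-exclusion strategies) at the end of
  the injection;
* *carried-over* windows — persistent for the remainder of the
  experiment.  These are either promoted DEW boxes (iterative exclusion)
  or the final bounding boxes of RoIs fragmented in earlier injections
  (multi-sample RoI exclusion), each carrying the precursor intensity of
  its fragmentation event(s).

``phi`` implements the maximum-intensity lookup used by the intensity
strategies; by construction it only ever consults carried-over windows.
Containment is closed-interval, consistent with :mod:`ddasim.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .geometry import Rect
from .roi import Roi


@dataclass(frozen=True)
class ExclusionWindow:
    rect: Rect
    intensity: float          # precursor intensity of the fragmentation event
    source_injection: int
    kind: Literal["dew", "roi_box"]

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("window intensity must be non-negative")


class _WindowSet:
    """A list of windows with lazily rebuilt NumPy bounds for fast queries."""

    def __init__(self) -> None:
        self.windows: list[ExclusionWindow] = []
        self._arrays: tuple[np.ndarray, ...] | None = None

    def add(self, w: ExclusionWindow) -> None:
        self.windows.append(w)
        self._arrays = None

    def extend(self, ws: Iterable[ExclusionWindow]) -> None:
        self.windows.extend(ws)
        self._arrays = None

    def _bounds(self) -> tuple[np.ndarray, ...]:
        if self._arrays is None:
            r = self.windows
            self._arrays = (
                np.array([w.rect.rt_lo for w in r]),
                np.array([w.rect.rt_hi for w in r]),
                np.array([w.rect.mz_lo for w in r]),
                np.array([w.rect.mz_hi for w in r]),
                np.array([w.intensity for w in r]),
            )
        return self._arrays

    def containing_mask(self, mz: float, rt: float) -> np.ndarray:
        rt_lo, rt_hi, mz_lo, mz_hi, _ = self._bounds()
        return (rt_lo <= rt) & (rt <= rt_hi) & (mz_lo <= mz) & (mz <= mz_hi)

    def contains_point(self, mz: float, rt: float) -> bool:
        if not self.windows:
            return False
        return bool(self.containing_mask(mz, rt).any())

    def max_intensity_at(self, mz: float, rt: float) -> float | None:
        if not self.windows:
            return None
        mask = self.containing_mask(mz, rt)
        if not mask.any():
            return None
        return float(self._bounds()[4][mask].max())

    def overlapping(self, rect: Rect) -> list[ExclusionWindow]:
        """Windows whose rects overlap ``rect`` with positive area."""
        if not self.windows:
            return []
        rt_lo, rt_hi, mz_lo, mz_hi, _ = self._bounds()
        mask = (rt_lo < rect.rt_hi) & (rect.rt_lo < rt_hi) & \
               (mz_lo < rect.mz_hi) & (rect.mz_lo < mz_hi)
        return [self.windows[i] for i in np.nonzero(mask)[0]]


class ExclusionRegistry:
    """Registry of exclusion windows threaded through a multi-injection run."""

    def __init__(self) -> None:
        self.within = _WindowSet()
        self.carried = _WindowSet()
        self._pending_rois: dict[int, Roi] = {}   # fragmented RoIs awaiting rollover
        self.injection = 0

    # --- queries ------------------------------------------------------
    def is_excluded(self, mz: float, rt: float, *,
                    within: bool = True, carried: bool = False) -> bool:
        """Containment truth behind the 0/1 exclusion indicator.

        True iff (mz, rt) lies inside any active window of the consulted
        population(s).  Expired within-injection DEWs cannot match: their
        rt span ends rt_tol seconds after the fragmentation event.
        """
        if within and self.within.contains_point(mz, rt):
            return True
        if carried and self.carried.contains_point(mz, rt):
            return True
        return False

    def phi(self, mz: float, rt: float) -> float | None:
        """Max intensity over carried-over windows containing the point.

        Returns None — "not previously fragmented" — when no carried
        window contains it; callers take the log term as 0.  Only
        between-injection windows are consulted, never DEWs.
        """
        return self.carried.max_intensity_at(mz, rt)

    def carried_overlapping(self, rect: Rect) -> list[ExclusionWindow]:
        return self.carried.overlapping(rect)

    # --- registration -------------------------------------------------
    def register_fragmentation(self, mz: float, rt: float, intensity: float, *,
                               mode: Literal["dew_box", "roi_box"],
                               roi: Roi | None = None,
                               mz_tol: float = 0.01,
                               rt_tol: float = 15.0) -> None:
        """Record a fragmentation event as exclusion state.

        dew_box adds a within-injection window [rt-rt_tol, rt+rt_tol] x
        [mz-mz_tol, mz+mz_tol].  The rt span is symmetric about the
        event: within an injection only the forward half can ever match
        (queries never precede the event), and when the box is promoted
        to a carried-over window the backward half is what lets it
        exclude the approach to the same peak in a later injection.
        roi_box queues the fragmented RoI so that its final bounds become
        a carried-over window (with the maximum of its event
        intensities) at injection rollover.
        """
        if mode == "dew_box":
            rect = Rect(rt - rt_tol, rt + rt_tol, mz - mz_tol, mz + mz_tol)
            self.within.add(ExclusionWindow(rect, intensity, self.injection, "dew"))
        elif mode == "roi_box":
            if roi is None:
                raise ValueError("roi_box registration requires a RoI")
            self._pending_rois[roi.id] = roi
        else:
            raise ValueError(f"unknown registration mode: {mode!r}")

    def end_injection(self, *, carry_dews: bool = False,
                      rt_pad: float = 0.0, mz_pad: float = 0.0) -> None:
        """Roll over to the next injection.

        Queued fragmented RoIs are frozen into carried-over roi_box
        windows from their final bounds (optionally padded).  With
        ``carry_dews`` the within-injection DEW boxes are promoted to
        carried-over windows (iterative exclusion); otherwise they are
        dropped.  Carried windows only ever accumulate.
        """
        for roi in self._pending_rois.values():
            b = roi.bounds
            rect = Rect(b.rt_lo - rt_pad, b.rt_hi + rt_pad,
                        b.mz_lo - mz_pad, b.mz_hi + mz_pad)
            self.carried.add(ExclusionWindow(
                rect, roi.max_frag_intensity, self.injection, "roi_box"))
        self._pending_rois.clear()
        if carry_dews:
            self.carried.extend(self.within.windows)
        self.within = _WindowSet()
        self.injection += 1

    # --- serialization ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": pop, "kind": w.kind,
             "rt_lo": w.rect.rt_lo, "rt_hi": w.rect.rt_hi,
             "mz_lo": w.rect.mz_lo, "mz_hi": w.rect.mz_hi,
             "intensity": w.intensity, "source_injection": w.source_injection}
            for pop, ws in (("within", self.within), ("carried", self.carried))
            for w in ws.windows
        ]
        return pd.DataFrame(rows, columns=["population", "kind", "rt_lo", "rt_hi",
                                           "mz_lo", "mz_hi", "intensity",
                                           "source_injection"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExclusionRegistry":
        reg = cls()
        df = pd.read_csv(path)
        for row in df.itertuples(index=False):
            w = ExclusionWindow(
                Rect(row.rt_lo, row.rt_hi, row.mz_lo, row.mz_hi),
                float(row.intensity), int(row.source_injection), row.kind)
            (reg.within if row.population == "within" else reg.carried).add(w)
        if len(df):
            reg.injection = int(df["source_injection"].max()) + 1
        return reg
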