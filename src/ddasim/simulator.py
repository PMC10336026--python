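"""Virtual LC-MS/MS instrument.

Advances a clock through alternating duty cycles — one MS1 survey scan,
then up to N controller-requested MS2 scans, each scan advancing the
clock by its fixed duration (defaults 0.59 s for MS1, 0.19 s for MS2).
MS1 intensities are each chemical's chromatogram evaluated at the scan's
retention time; an MS2 event's precursor intensity is the most intense
model point inside the isolation window at the moment the MS2 scan runs.
Multi-injection experiments thread carried-over exclusion state through
the controller between injections.

Runs are deterministic: with no retention-time jitter the same inputs
reproduce the same scan and event sequence bit for bit; optional
per-injection rt jitter is driven entirely by the experiment seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemicals import Chemical
from .controllers import Controller, ControllerConfig
from .roi import Ms1Point

EVENT_COLUMNS = ["injection", "sample", "rt", "precursor_mz",
                 "precursor_intensity", "strategy", "target_roi_id"]
_EVENT_DTYPES = {"injection": "int64", "sample": "object", "rt": "float64",
                 "precursor_mz": "float64", "precursor_intensity": "float64",
                 "strategy": "object", "target_roi_id": "int64"}


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _EVENT_DTYPES.items()})


@dataclass
class Scan:
    """One acquired scan: an MS1 point list or an MS2 isolation event."""

    ms_level: int
    rt: float
    mzs: np.ndarray | None = None            # MS1 only, sorted
    intensities: np.ndarray | None = None    # MS1 only
    precursor_mz: float | None = None        # MS2 only
    precursor_intensity: float | None = None
    isolation_width: float | None = None


@dataclass
class InjectionSchedule:
    """Injection order and fixed per-scan timings of an experiment."""

    sample_order: Sequence[str]
    max_rt: float = 150.0
    ms1_duration: float = 0.59
    ms2_duration: float = 0.19

    def __post_init__(self) -> None:
        if self.ms1_duration <= 0 or self.ms2_duration <= 0 or self.max_rt <= 0:
            raise ValueError("durations and max_rt must be positive")


@dataclass
class InjectionResult:
    injection: int
    sample: str
    scans: list[Scan]
    events: pd.DataFrame


@dataclass
class ExperimentResult:
    injections: list[InjectionResult]
    events: pd.DataFrame       # concatenated, EVENT_COLUMNS schema
    config: ControllerConfig
    schedule: InjectionSchedule

    @property
    def n_injections(self) -> int:
        return len(self.injections)


class _SampleModel:
    """Vectorized chromatogram evaluation for one sample's chemicals."""

    def __init__(self, chemicals: Sequence[Chemical], rt_shift: float = 0.0):
        self.chems = sorted(chemicals, key=lambda c: c.mz)
        self.mzs = np.array([c.mz for c in self.chems])
        self.apex = np.array([c.apex_intensity for c in self.chems])
        self.apex_rt = np.array([c.apex_rt for c in self.chems]) + rt_shift
        self.sigma = np.array([c.sigma for c in self.chems])
        self._empirical = [i for i, c in enumerate(self.chems)
                           if c.profile_rt is not None]
        self.rt_shift = rt_shift

    def intensities_at(self, rt: float) -> np.ndarray:
        z = (rt - self.apex_rt) / self.sigma
        out = self.apex * np.exp(-0.5 * z * z)
        for i in self._empirical:
            out[i] = self.chems[i].intensity_at(rt - self.rt_shift)
        return out

    def ms1_points(self, rt: float, floor: float) -> list[Ms1Point]:
        inten = self.intensities_at(rt)
        mask = inten > floor if floor > 0 else inten > 0.0
        return [Ms1Point(float(m), rt, float(i))
                for m, i in zip(self.mzs[mask], inten[mask])]

    def precursor_intensity(self, mz: float, width: float, rt: float) -> float:
        """Most intense model point inside the isolation window at rt."""
        half = 0.5 * width
        lo = np.searchsorted(self.mzs, mz - half, side="left")
        hi = np.searchsorted(self.mzs, mz + half, side="right")
        if hi <= lo:
            return 0.0
        return float(self.intensities_at(rt)[lo:hi].max())


def run_injection(chemicals: Sequence[Chemical], controller: Controller,
                  schedule: InjectionSchedule, *, injection: int = 0,
                  sample: str = "S1", detection_floor: float = 0.0,
                  rt_shift: float = 0.0, keep_scans: bool = True
                  ) -> InjectionResult:
    """Simulate one injection; controller state is mutated in place.

    The caller is responsible for ``controller.begin_injection()`` /
    ``end_injection()`` when sequencing multiple injections.
    """
    model = _SampleModel(chemicals, rt_shift)
    scans: list[Scan] = []
    event_rows: list[tuple] = []
    t = 0.0
    while t <= schedule.max_rt:
        points = model.ms1_points(t, detection_floor)
        if keep_scans:
            scans.append(Scan(1, t,
                              mzs=np.array([p.mz for p in points]),
                              intensities=np.array([p.intensity for p in points])))
        requests = controller.process_ms1(points, t)
        t += schedule.ms1_duration
        for req in requests:
            if t > schedule.max_rt:
                break
            inten = model.precursor_intensity(
                req.precursor_mz, req.isolation_width, t)
            if keep_scans:
                scans.append(Scan(2, t, precursor_mz=req.precursor_mz,
                                  precursor_intensity=inten,
                                  isolation_width=req.isolation_width))
            controller.ms2_performed(req, t, inten)
            event_rows.append((injection, sample, t, req.precursor_mz, inten,
                               controller.cfg.strategy,
                               req.target_roi.id if req.target_roi else -1))
            t += schedule.ms2_duration
    events = (pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
              if event_rows else _empty_events())
    return InjectionResult(injection, sample, scans, events)


def run_experiment(samples: Mapping[str, Sequence[Chemical]],
                   schedule: InjectionSchedule, cfg: ControllerConfig, *,
                   detection_floor: float = 0.0, rt_jitter_sd: float = 0.0,
                   seed: int = 0, keep_scans: bool = False) -> ExperimentResult:
    """Run a multi-injection experiment with cross-injection carryover.

    Injections execute in ``schedule.sample_order``; the strategy's
    carried-over exclusion state is threaded through the controller.  By
    default there is no retention-time noise between injections;
    ``rt_jitter_sd`` adds a seeded per-injection Gaussian rt shift.
    """
    for sid in schedule.sample_order:
        if sid not in samples:
            raise KeyError(f"unknown sample id: {sid!r}")
    rng = np.random.default_rng(seed)
    controller = Controller(cfg)
    results: list[InjectionResult] = []
    for k, sid in enumerate(schedule.sample_order):
        shift = float(rng.normal(0.0, rt_jitter_sd)) if rt_jitter_sd > 0 else 0.0
        controller.begin_injection()
        res = run_injection(samples[sid], controller, schedule,
                            injection=k, sample=sid,
                            detection_floor=detection_floor,
                            rt_shift=shift, keep_scans=keep_scans)
        controller.end_injection()
        results.append(res)
    frames = [r.events for r in results if len(r.events)]
    events = (pd.concat(frames, ignore_index=True) if frames
              else _empty_events())
    return ExperimentResult(results, events, cfg, schedule)
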