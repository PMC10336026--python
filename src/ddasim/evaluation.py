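"""Coverage metrics of fragmentation-event logs against aligned peak lists.

Two headline metrics, both cumulative over injections and in [0, 1]:

* **peak coverage** — the fraction of aligned peak rows for which at
  least one fragmentation event (in any sample where the row has a box)
  has fallen inside the row's box so far;
* **intensity coverage** — how close to apex the spectra were acquired:
  the sum over rows of the best matched precursor intensity (0 if the
  row is uncovered, capped at the row's apex) divided by the sum of row
  apex intensities.  A row present in several samples contributes its
  largest per-sample apex to the denominator and its best match across
  samples to the numerator.

An aligned row is matched by an event when the event's sample has a box
for that row and the event's (m/z, rt) lies inside it (closed bounds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import Rect

PEAK_COLUMNS = ["row_id", "sample", "rt_lo", "rt_hi", "mz_lo", "mz_hi",
                "apex_intensity"]


@dataclass(frozen=True)
class PickedPeak:
    row_id: int
    sample: str
    box: Rect
    apex_intensity: float

    def __post_init__(self) -> None:
        if self.apex_intensity <= 0:
            raise ValueError("apex_intensity must be positive")


@dataclass
class CoverageReport:
    """Per-injection cumulative coverage series for one strategy."""

    coverage: np.ndarray             # cumulative fraction per injection
    intensity_coverage: np.ndarray
    best_intensity: Mapping[int, float]   # per row, final best matched (capped)
    n_rows: int
    total_apex: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "injection": np.arange(len(self.coverage)),
            "coverage": self.coverage,
            "intensity_coverage": self.intensity_coverage,
        })


def peaks_from_frame(df: pd.DataFrame) -> list[PickedPeak]:
    return [PickedPeak(int(r.row_id), str(r.sample),
                       Rect(r.rt_lo, r.rt_hi, r.mz_lo, r.mz_hi),
                       float(r.apex_intensity))
            for r in df.itertuples(index=False)]


def coverage(events: pd.DataFrame, peaks: pd.DataFrame,
             n_injections: int | None = None) -> CoverageReport:
    """Score an event log against an aligned peak list.

    ``events`` needs columns (injection, sample, rt, precursor_mz,
    precursor_intensity); ``peaks`` follows PEAK_COLUMNS.  Events in a
    sample absent from the peak list raise.  ``n_injections`` defaults
    to one past the largest injection index seen in the events.
    """
    for col in PEAK_COLUMNS:
        if col not in peaks.columns:
            raise ValueError(f"peak list missing column {col!r}")
    if n_injections is None:
        n_injections = int(events["injection"].max()) + 1 if len(events) else 1

    row_ids = np.sort(peaks["row_id"].unique())
    row_pos = {rid: i for i, rid in enumerate(row_ids)}
    n_rows = len(row_ids)
    # denominator apex per row: max over the samples it appears in
    row_apex = peaks.groupby("row_id")["apex_intensity"].max()
    row_apex = row_apex.reindex(row_ids).to_numpy()
    total_apex = float(row_apex.sum())

    peak_samples = set(peaks["sample"].unique())
    if len(events):
        unknown = set(events["sample"].unique()) - peak_samples
        if unknown:
            raise ValueError(f"events reference unknown sample ids: {sorted(unknown)}")

    # best matched intensity per (row, injection), capped at the row apex
    best = np.zeros((n_rows, n_injections))
    for sample, ev in (events.groupby("sample") if len(events) else []):
        pk = peaks[peaks["sample"] == sample]
        if not len(pk):
            continue
        p_rt_lo = pk["rt_lo"].to_numpy()[:, None]
        p_rt_hi = pk["rt_hi"].to_numpy()[:, None]
        p_mz_lo = pk["mz_lo"].to_numpy()[:, None]
        p_mz_hi = pk["mz_hi"].to_numpy()[:, None]
        e_rt = ev["rt"].to_numpy()[None, :]
        e_mz = ev["precursor_mz"].to_numpy()[None, :]
        hit = (p_rt_lo <= e_rt) & (e_rt <= p_rt_hi) & \
              (p_mz_lo <= e_mz) & (e_mz <= p_mz_hi)
        if not hit.any():
            continue
        e_int = ev["precursor_intensity"].to_numpy()
        e_inj = ev["injection"].to_numpy().astype(int)
        pk_rows = pk["row_id"].to_numpy()
        pk_apex = pk["apex_intensity"].to_numpy()
        pi, ei = np.nonzero(hit)
        matched = np.minimum(e_int[ei], pk_apex[pi])
        rows = np.array([row_pos[r] for r in pk_rows[pi]])
        np.maximum.at(best, (rows, e_inj[ei]), matched)

    # cumulative over injections
    best_cum = np.maximum.accumulate(best, axis=1)
    cov = (best_cum > 0).sum(axis=0) / n_rows if n_rows else np.zeros(n_injections)
    icov = best_cum.sum(axis=0) / total_apex if total_apex > 0 \
        else np.zeros(n_injections)
    final_best = {int(rid): float(best_cum[row_pos[rid], -1]) for rid in row_ids}
    return CoverageReport(cov, icov, final_best, n_rows, total_apex)


def compare_strategies(reports: Mapping[str, CoverageReport]) -> pd.DataFrame:
    """Tabulate per-injection metrics and deltas against the first strategy."""
    names = list(reports)
    lengths = {len(r.coverage) for r in reports.values()}
    if len(lengths) > 1:
        raise ValueError("reports cover different numbers of injections")
    n_rows = {r.n_rows for r in reports.values()}
    if len(n_rows) > 1:
        raise ValueError("reports scored against different peak lists")
    base = reports[names[0]]
    frames = []
    for name in names:
        r = reports[name]
        df = r.to_frame()
        df.insert(0, "strategy", name)
        df["coverage_delta"] = r.coverage - base.coverage
        df["intensity_coverage_delta"] = r.intensity_coverage - base.intensity_coverage
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
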