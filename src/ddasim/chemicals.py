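"""Ground-truth chemical mixtures and seeded multi-sample cohorts.

A :class:`Chemical` is one ionized species with a chromatographic
elution profile: Gaussian by default (apex intensity at ``apex_rt``,
width ``sigma``), or an empirical interpolated profile when imported
from a fullscan mzML.  A cohort is a set of samples sharing some
chemicals (present in all samples, with per-sample log-normal intensity
factors) and owning some unique ones — the structure of a multi-sample
metabolomics batch with partial overlap in metabolites.

The generator also emits the aligned picked-peak list the evaluation
module scores against: one row per chemical, one box per sample where it
is present, with rt bounds apex_rt +/- 3 sigma and the per-sample apex
height.  Alignment is by construction (same chemical id <=> same row),
standing in for peak-picking and alignment of real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: rt half-width of a truth box, in chromatographic sigmas; covers >99%
#: of a Gaussian profile, mimicking picked-peak rt bounds
TRUTH_BOX_K_SIGMA = 3.0
#: m/z half-width of a truth box, Da
TRUTH_BOX_MZ_TOL = 0.01


@dataclass
class Chemical:
    """One ground-truth species with a chromatographic elution profile."""

    id: int
    mz: float
    apex_rt: float
    apex_intensity: float
    sigma: float = 10.0
    # empirical profile (rt, intensity) arrays; overrides the Gaussian
    profile_rt: np.ndarray | None = None
    profile_intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.apex_intensity <= 0:
            raise ValueError("apex_intensity must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mz <= 0:
            raise ValueError("mz must be positive")

    def intensity_at(self, rt: float) -> float:
        if self.profile_rt is not None:
            return float(np.interp(rt, self.profile_rt, self.profile_intensity,
                                   left=0.0, right=0.0))
        z = (rt - self.apex_rt) / self.sigma
        return self.apex_intensity * math.exp(-0.5 * z * z)

    def scaled(self, factor: float) -> "Chemical":
        """Copy with apex (and any empirical profile) scaled by ``factor``."""
        prof = None if self.profile_intensity is None \
            else self.profile_intensity * factor
        return replace(self, apex_intensity=self.apex_intensity * factor,
                       profile_intensity=prof)


@dataclass
class CohortConfig:
    """Study-design knobs for a seeded synthetic cohort.

    Defaults describe a desk-scale but oversubscribed metabolomics
    batch — more eluting peaks than MS2 capacity, the regime DDA
    scheduling is for: m/z 70-1000, a 150 s gradient with ~300 chemicals
    (peak arrival comparable to the ~4 MS2/s duty-cycle capacity at
    N=10), log-normal apex intensities (median 5e5 counts, sigma_ln
    1.5), chromatographic sigma uniform on 3-10 s, and per-sample
    intensity factors log-normal with sigma_ln 0.3.  Chemicals are
    spaced at least ``min_mz_spacing`` apart in m/z (default twice a
    0.7 m/z isolation width) so ground truth is unambiguous.
    """

    n_samples: int = 1
    n_shared: int = 300
    n_unique_per_sample: int = 0
    mz_range: tuple[float, float] = (70.0, 1000.0)
    rt_range: tuple[float, float] = (0.0, 150.0)
    log_intensity_mean: float = math.log(5e5)
    log_intensity_sigma: float = 1.5
    sigma_range: tuple[float, float] = (3.0, 10.0)
    sample_factor_sigma: float = 0.3
    min_mz_spacing: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_shared, self.n_unique_per_sample) < 0 \
                or self.n_samples == 0:
            raise ValueError("counts must be non-negative, n_samples >= 1")


def _spaced_mzs(rng: np.random.Generator, n: int, lo: float, hi: float,
                spacing: float) -> np.ndarray:
    """Draw n m/z values pairwise separated by at least ``spacing``.

    Uniform order statistics on the spacing-shrunk range, shifted back by
    i * spacing — the uniform distribution conditioned on the minimum
    spacing constraint.
    """
    if n == 0:
        return np.empty(0)
    slack = (hi - lo) - (n - 1) * spacing
    if slack <= 0:
        raise ValueError("m/z range too narrow for requested spacing")
    base = np.sort(rng.uniform(lo, lo + slack, size=n))
    return base + spacing * np.arange(n)


def generate_cohort(cfg: CohortConfig) -> tuple[dict[str, list[Chemical]],
                                                pd.DataFrame]:
    """Generate a seeded cohort and its aligned truth-peak table.

    Returns ``(samples, truth_peaks)`` where ``samples`` maps sample id
    ("S1", "S2", ...) to that sample's chemicals (apexes already scaled
    by the per-sample factor) and ``truth_peaks`` has one row per
    (chemical, sample-with-presence) with columns: row_id, sample,
    rt_lo, rt_hi, mz_lo, mz_hi, apex_intensity.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_shared + cfg.n_samples * cfg.n_unique_per_sample
    mzs = _spaced_mzs(rng, n_total, *cfg.mz_range, cfg.min_mz_spacing)
    # shuffle so shared/unique assignment is not ordered in m/z
    mzs = rng.permutation(mzs)

    sigmas = rng.uniform(*cfg.sigma_range, size=n_total)
    # keep apexes fully eluting inside the run
    pad = TRUTH_BOX_K_SIGMA * cfg.sigma_range[1]
    rt_lo, rt_hi = cfg.rt_range[0] + pad, cfg.rt_range[1] - pad
    apex_rts = rng.uniform(rt_lo, rt_hi, size=n_total)
    apex_int = np.exp(rng.normal(cfg.log_intensity_mean,
                                 cfg.log_intensity_sigma, size=n_total))

    base = [Chemical(i, float(mzs[i]), float(apex_rts[i]), float(apex_int[i]),
                     float(sigmas[i])) for i in range(n_total)]
    sample_ids = [f"S{k + 1}" for k in range(cfg.n_samples)]

    # presence structure: first n_shared in all samples, then blocks of
    # n_unique_per_sample owned by one sample each
    presence: dict[int, list[str]] = {}
    for i in range(cfg.n_shared):
        presence[i] = list(sample_ids)
    for k, sid in enumerate(sample_ids):
        start = cfg.n_shared + k * cfg.n_unique_per_sample
        for i in range(start, start + cfg.n_unique_per_sample):
            presence[i] = [sid]

    samples: dict[str, list[Chemical]] = {sid: [] for sid in sample_ids}
    rows = []
    for chem in base:
        for sid in presence[chem.id]:
            factor = float(np.exp(rng.normal(0.0, cfg.sample_factor_sigma)))
            inst = chem.scaled(factor)
            samples[sid].append(inst)
            half = TRUTH_BOX_K_SIGMA * chem.sigma
            rows.append({
                "row_id": chem.id, "sample": sid,
                "rt_lo": chem.apex_rt - half, "rt_hi": chem.apex_rt + half,
                "mz_lo": chem.mz - TRUTH_BOX_MZ_TOL,
                "mz_hi": chem.mz + TRUTH_BOX_MZ_TOL,
                "apex_intensity": inst.apex_intensity,
            })
    for sid in sample_ids:
        samples[sid].sort(key=lambda c: c.mz)
    truth = pd.DataFrame(rows, columns=["row_id", "sample", "rt_lo", "rt_hi",
                                        "mz_lo", "mz_hi", "apex_intensity"])
    return samples, truth


def chemicals_from_fullscan(path, roi_params=None, min_points: int = 2) -> list[Chemical]:
    """Convert a fullscan mzML into chemicals with empirical profiles.

    Builds RoIs from the MS1 stream and turns each RoI with at least
    ``min_points`` points into a Chemical whose chromatogram linearly
    interpolates the RoI's points.  Simulating a fullscan-only run from
    these chemicals and re-extracting RoIs recovers the original apexes.
    """
    from .mzml import read_fullscan_mzml
    from .roi import Ms1Point, RoiBuilder, RoiParams

    builder = RoiBuilder(roi_params or RoiParams())
    n_scans = 0
    for scan in read_fullscan_mzml(path):
        n_scans += 1
        builder.process_scan([Ms1Point(mz, scan.rt, i)
                              for mz, i in zip(scan.mzs, scan.intensities)])
    if n_scans == 0:
        raise ValueError(f"no MS1 scans in {path}")
    builder.close_all()

    chems = []
    for roi in builder.all_rois:
        if roi.n_points < min_points:
            continue
        idx = int(np.argmax(roi.intensities))
        chems.append(Chemical(
            id=roi.id, mz=float(np.mean(roi.mzs)),
            apex_rt=float(roi.rts[idx]),
            apex_intensity=float(roi.intensities[idx]),
            sigma=max(1.0, (roi.rts[-1] - roi.rts[0]) / (2 * TRUTH_BOX_K_SIGMA)),
            profile_rt=np.asarray(roi.rts, dtype=float),
            profile_intensity=np.asarray(roi.intensities, dtype=float)))
    chems.sort(key=lambda c: c.mz)
    return chems


def chemicals_to_frame(samples: Mapping[str, Sequence[Chemical]]) -> pd.DataFrame:
    rows = [{"sample": sid, "id": c.id, "mz": c.mz, "apex_rt": c.apex_rt,
             "apex_intensity": c.apex_intensity, "sigma": c.sigma}
            for sid, chems in samples.items() for c in chems]
    return pd.DataFrame(rows, columns=["sample", "id", "mz", "apex_rt",
                                       "apex_intensity", "sigma"])


def chemicals_from_frame(df: pd.DataFrame) -> dict[str, list[Chemical]]:
    samples: dict[str, list[Chemical]] = {}
    for row in df.itertuples(index=False):
        samples.setdefault(str(row.sample), []).append(Chemical(
            int(row.id), float(row.mz), float(row.apex_rt),
            float(row.apex_intensity), float(row.sigma)))
    for chems in samples.values():
        chems.sort(key=lambda c: c.mz)
    return samples
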