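"""Packaged experiment designs: benchmarks the rest of the package replays.

Two desk-scale study designs mirror the canonical multi-injection
benchmarks for multi-sample DDA exclusion:

* **same-sample** — one sample of ~300 chemicals injected repeatedly
  (default 10 injections).  With no retention-time noise, a plain TopN
  run is identical every injection, so its cumulative coverage is flat;
  carryover strategies keep finding new peaks, and intensity-aware
  strategies keep raising intensity coverage after coverage plateaus.
* **6x4 multi-sample** — six samples with partial metabolite overlap
  (250 shared + 50 unique chemicals each), injected four times each in
  the interleaved order S1-S2-S3-S4-S5-S6-S1-S2-S3-S4..., so no sample
  ever leads another by more than one repeat.

Scan durations are fixed at 0.59 s (MS1) and 0.19 s (MS2), N = 10,
lambda_min = 5000 counts.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import pandas as pd

from .chemicals import Chemical, CohortConfig, generate_cohort
from .controllers import ControllerConfig, STRATEGIES
from .evaluation import CoverageReport, coverage
from .simulator import ExperimentResult, InjectionSchedule, run_experiment


def same_sample_design(seed: int = 0, n_injections: int = 10,
                       n_chemicals: int = 300
                       ) -> tuple[dict[str, list[Chemical]], pd.DataFrame,
                                  InjectionSchedule]:
    cohort = CohortConfig(n_samples=1, n_shared=n_chemicals,
                          n_unique_per_sample=0, seed=seed)
    samples, truth = generate_cohort(cohort)
    schedule = InjectionSchedule(["S1"] * n_injections)
    return samples, truth, schedule


def multi_sample_design(seed: int = 0, n_samples: int = 6, n_repeats: int = 4,
                        n_shared: int = 250, n_unique: int = 50
                        ) -> tuple[dict[str, list[Chemical]], pd.DataFrame,
                                   InjectionSchedule]:
    cohort = CohortConfig(n_samples=n_samples, n_shared=n_shared,
                          n_unique_per_sample=n_unique, seed=seed)
    samples, truth = generate_cohort(cohort)
    order = [f"S{(k % n_samples) + 1}" for k in range(n_samples * n_repeats)]
    schedule = InjectionSchedule(order)
    return samples, truth, schedule


def run_strategy(samples: Mapping[str, Sequence[Chemical]],
                 truth: pd.DataFrame, schedule: InjectionSchedule,
                 strategy: str, *, seed: int = 0,
                 base_cfg: ControllerConfig | None = None
                 ) -> tuple[ExperimentResult, CoverageReport]:
    cfg = replace(base_cfg or ControllerConfig(), strategy=strategy)
    result = run_experiment(samples, schedule, cfg, seed=seed)
    report = coverage(result.events, truth,
                      n_injections=len(schedule.sample_order))
    return result, report


def run_benchmark(samples, truth, schedule,
                  strategies: Sequence[str] = STRATEGIES, *, seed: int = 0,
                  base_cfg: ControllerConfig | None = None
                  ) -> dict[str, CoverageReport]:
    """Run several strategies on one design; reports share the peak list."""
    return {s: run_strategy(samples, truth, schedule, s, seed=seed,
                            base_cfg=base_cfg)[1]
            for s in strategies}
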