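"""Experiment configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .chemicals import CohortConfig
from .controllers import ControllerConfig
from .roi import DewConfig, RoiParams
from .simulator import InjectionSchedule


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment from a file."""

    controller: ControllerConfig = field(default_factory=ControllerConfig)
    schedule: InjectionSchedule = field(
        default_factory=lambda: InjectionSchedule(["S1"]))
    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    fullscan_paths: list[str] = field(default_factory=list)
    output_dir: str = "out"
    seed: int = 0
    detection_floor: float = 0.0
    rt_jitter_sd: float = 0.0
    log_level: str = "INFO"

    # --- (de)serialization -------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"]["sample_order"] = list(d["schedule"]["sample_order"])
        for key in ("mz_range", "rt_range", "sigma_range"):
            if d["cohort"] is not None:
                d["cohort"][key] = list(d["cohort"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        ctrl = dict(d.pop("controller", {}))
        dew = DewConfig(**ctrl.pop("dew", {}))
        roi = RoiParams(**ctrl.pop("roi", {}))
        controller = ControllerConfig(dew=dew, roi=roi, **ctrl)
        schedule = InjectionSchedule(**d.pop("schedule", {"sample_order": ["S1"]}))
        cohort_d = d.pop("cohort", None)
        cohort = None
        if cohort_d is not None:
            cohort_d = dict(cohort_d)
            for key in ("mz_range", "rt_range", "sigma_range"):
                if key in cohort_d:
                    cohort_d[key] = tuple(cohort_d[key])
            cohort = CohortConfig(**cohort_d)
        known = {f.name for f in fields(cls)} - {"controller", "schedule", "cohort"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(controller=controller, schedule=schedule, cohort=cohort, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
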