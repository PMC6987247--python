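"""Run configuration with the study protocol as defaults.

Defaults reproduce the measurement/analysis protocol: 5 mm analysis pupil,
555 nm, vergence sweep from 4 D hyperopia to 4 D myopia in 0.5 D steps, DOF
threshold at 70% of peak NS, 256 pupil samples with 8× zero-padding and a
1-arcmin neural weighting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    pupil_diameter_mm: float = 5.0
    wavelength_um: float = 0.555
    vergence_min_d: float = -4.0
    vergence_max_d: float = 4.0
    vergence_step_d: float = 0.5
    threshold_fraction: float = 0.70
    threshold_scale: str = "ns"          # "ns" or "logns"
    psf_samples_across_pupil: int = 256
    psf_pad_factor: int = 8
    psf_max_samples: int = 1024          # cap for automatic sampling escalation
    metric_sigma_arcmin: float = 1.0
    seed: int = 0
    include_control_left_eye: bool = False
    # per-preset overrides, e.g. {"KCE_unaided": {"n_subjects": 5}}
    cohort_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pupil_diameter_mm <= 0 or self.wavelength_um <= 0:
            raise ValueError("pupil diameter and wavelength must be positive")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.vergence_min_d >= self.vergence_max_d or self.vergence_step_d <= 0:
            raise ValueError("invalid vergence range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
        return cls.from_dict(data)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
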