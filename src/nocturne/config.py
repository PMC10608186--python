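"""Pipeline configuration with YAML round-trip.

All thresholds default to the analysis conventions used throughout the
package; a YAML file may override any subset of them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # device / extraction
    device_min: float = 2.2
    device_max: float = 22.0
    cadence_min: float = 5.0
    cadence_tol_s: float = 90.0
    oor_policy: str = "missing"  # reject | clamp | missing
    # exclusion
    gap_run_exclude: int = 3
    missing_frac_exclude: float = 0.10
    # NH detection
    nh_threshold: float = 3.9
    min_duration_min: float = 15.0
    # clustering
    k_min: int = 2
    k_max: int = 15
    k_override_nh: int | None = None
    k_override_non_nh: int | None = None
    # Monte Carlo
    n_reps: int = 100
    quantile_level: float = 0.95
    max_lag: int = 3
    bias_correct: bool = True
    # reproducibility
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
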