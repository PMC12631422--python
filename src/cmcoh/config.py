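"""Run configuration: every pipeline knob with its default, validated
strictly (unknown keys are rejected before any computation)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, field_validator


class RunConfig(BaseModel):
    """All tunables of a synth → preprocess → spectral → stats run."""

    model_config = ConfigDict(extra="forbid")

    # synth
    n_subjects: int = 8
    n_trials: int = 20
    fs: float = 1000.0
    coupling_band: tuple[float, float] = (13.0, 19.0)
    coupling_delay_ms: float = 10.0
    planted_correlation: float = 0.8
    planted_covariate: str = "injury"
    target_region: str = "M1"
    target_muscle: str = "flexor_digitorum"
    seed: int = 0

    # preprocess
    eeg_band: tuple[float, float] = (0.5, 50.0)
    emg_band: tuple[float, float] = (10.0, 100.0)
    filter_order: int = 4
    amplitude_threshold_uv: float | None = 200.0
    precleaned: bool = False
    apply_laplacian: bool = True
    pre_ms: float = 1000.0
    post_ms: float = 4000.0
    roi_map_path: str | None = None

    # spectral
    segment_s: float = 1.0
    task_window_ms: tuple[float, float] = (0.0, 4000.0)

    # stats
    q: float = 0.05
    power_method: str = "exact"
    min_subgroup_n: int = 4
    gate_alpha: float = 0.05

    @field_validator("power_method")
    @classmethod
    def _check_power_method(cls, v: str) -> str:
        if v not in ("exact", "fisher_z"):
            raise ValueError(f"power_method must be 'exact' or 'fisher_z', got {v!r}")
        return v

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.model_validate(json.load(f))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
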