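"""Run configuration: a flat, YAML-serializable parameter record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; round-trips through YAML."""

    # spectral axis
    axis_start_cm1: float = 400.0
    axis_stop_cm1: float = 3200.0
    axis_step_cm1: float = 1.0
    # baseline correction
    baseline_lambda: float = 1e8
    baseline_p: float = 0.01
    baseline_iterations: int = 10
    # phenotype thresholds
    cdr_threshold: float = 0.05
    snr_threshold_k: float = 5.0
    sort_criterion: str = "cd_band"
    # synthetic community
    n_cells: int = 20
    noise_sd: float = 0.05
    p_mda_success: float = 0.43
    # QC rounding
    table_decimals: int = 2
    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the resolved configuration, for run logs."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
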