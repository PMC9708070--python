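"""Pipeline configuration with the study's fixed constants as defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 1)."""


@dataclasses.dataclass
class PipelineConfig:
    theta: float = 1.0  # max average within-subtype dissimilarity
    min_size: int = 20  # minimum subtype membership
    fd_threshold: float = 0.4  # mm, frame-censoring cutoff
    qc_min_frames: int = 50
    qc_max_mean_fd: float = 0.3  # mm
    fdr_q: float = 0.05
    ci_level_ladder: float = 0.90
    ci_level_bars: float = 0.95
    covariates: tuple = ("site", "age", "mean_fd")
    whole_brain_fc: bool = False
    rng_seed: int = 0
    n_subsamples: int = 1000
    n_pairs: int = 1000
    M: int = 1
    K: int = 1

    def __post_init__(self):
        if not (0 < self.theta <= 2):
            raise ConfigError(f"theta must be in (0, 2], got {self.theta}")
        if self.min_size < 1:
            raise ConfigError("min_size must be >= 1")
        if not (0 < self.fdr_q < 1):
            raise ConfigError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        for lvl in (self.ci_level_ladder, self.ci_level_bars):
            if not (0 < lvl < 1):
                raise ConfigError(f"CI level must be in (0, 1), got {lvl}")
        if not (1 <= self.K <= self.M):
            raise ConfigError(f"need 1 <= K <= M, got K={self.K}, M={self.M}")
        self.covariates = tuple(self.covariates)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(d["covariates"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        try:
            if path.suffix in (".yaml", ".yml"):
                data = yaml.safe_load(path.read_text()) or {}
            else:
                data = json.loads(path.read_text())
        except Exception as exc:  # noqa: BLE001
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
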