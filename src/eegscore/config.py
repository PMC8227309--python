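"""Pipeline configuration: a YAML-serializable parameter bundle.

One seed in the config fans out to per-stage substreams inside the
library (each stage derives its generator from ``[seed, stage-tag]``),
so stages re-run in isolation reproduce the full run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PreprocessingParams:
    low: float = 0.1
    high: float = 100.0
    order: int = 4
    kappa: float = 15.0
    calib_segment: str = "EO"
    window_s: float = 1.0

    def validate(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("need 0 < low < high")
        if self.order < 1 or self.kappa <= 0 or self.window_s <= 0:
            raise ValueError("order, kappa and window_s must be positive")
        if self.calib_segment not in ("EC", "EO"):
            raise ValueError("calibration segment must be EC or EO")


@dataclass
class ModelParams:
    K: int = 4
    n_iter: int = 10
    train_frac: float = 0.7
    n_subsamples: int = 30

    def validate(self) -> None:
        if self.K < 1 or self.n_iter < 1 or self.n_subsamples < 1:
            raise ValueError("K, n_iter and n_subsamples must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


@dataclass
class PipelineConfig:
    n_text: int = 10
    n_video: int = 10
    seed: int = 0
    artifact_rate: float = 2.0  # events/min injected into learning tasks
    artifact_amplitude: float = 30.0
    alpha: float = 0.05
    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    model: ModelParams = field(default_factory=ModelParams)
    write_eeg: bool = False  # EDF per participant is bulky; off by default

    def validate(self) -> None:
        if self.n_text < 1 or self.n_video < 1:
            raise ValueError("participant counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        self.preprocessing.validate()
        self.model.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pre = d.pop("preprocessing", {})
        model = d.pop("model", {})
        cfg = cls(
            preprocessing=PreprocessingParams(**pre), model=ModelParams(**model), **d
        )
        cfg.validate()
        return cfg

    def save(self, path: Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
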