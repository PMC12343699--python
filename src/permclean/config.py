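"""Pipeline configuration: every tunable in one serializable object.

The defaults reproduce the recommended operating point for 1-minute
permittivity data: Gaussian causal smoothing with w = 70 (σ = w/5), an
overlapping mean-DRA with w1 = 1 and w2 = 15, a two-sided static threshold of
1.06 pF/cm, and 15-sample replacement and validation windows.  Configurations
round-trip losslessly through plain-text YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .detection import ThresholdSpec
from .dra import DraSpec
from .errors import ParameterError
from .smoothing import SmootherSpec


@dataclass(frozen=True)
class PipelineConfig:
    smoother: SmootherSpec = field(default_factory=SmootherSpec)
    dra: DraSpec = field(default_factory=DraSpec)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    validation_len: int = 15
    replacement_window: int = 15
    sample_period_s: float = 60.0

    def __post_init__(self) -> None:
        if int(self.validation_len) < 1:
            raise ParameterError("validation_len must be >= 1")
        if int(self.replacement_window) < 1:
            raise ParameterError("replacement_window must be >= 1")
        if not self.sample_period_s > 0:
            raise ParameterError("sample_period_s must be > 0")

    @property
    def period_min(self) -> float:
        return self.sample_period_s / 60.0

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "smoother": asdict(self.smoother),
            "dra": asdict(self.dra),
            "threshold": asdict(self.threshold),
            "validation_len": self.validation_len,
            "replacement_window": self.replacement_window,
            "sample_period_s": self.sample_period_s,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {"smoother", "dra", "threshold", "validation_len",
                 "replacement_window", "sample_period_s"}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "smoother" in data:
            kwargs["smoother"] = SmootherSpec(**data["smoother"])
        if "dra" in data:
            kwargs["dra"] = DraSpec(**data["dra"])
        if "threshold" in data:
            kwargs["threshold"] = ThresholdSpec(**data["threshold"])
        for key in ("validation_len", "replacement_window", "sample_period_s"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})
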