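"""Run configuration: every knob of the pipeline in one serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .fusion import CVConfig
from .importance import COMPARATOR_METHODS
from .network import HyperParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Full pipeline configuration; YAML round-trips losslessly."""

    hyperparams: HyperParams = field(default_factory=HyperParams)
    r: float = 0.3
    score_method: str = "pagerank"
    cv: CVConfig = field(default_factory=CVConfig)
    output_dir: Path = Path("unibrainnet_run")
    log_level: str = "INFO"
    standardize: bool = True
    align: bool = True
    # threshold r as a fraction of the largest edge strength (scale-free);
    # set False to cut at the raw value r
    relative_threshold: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0):
            raise ValidationError(f"threshold r must be in [0, 1], got {self.r}")
        if self.score_method not in ("pagerank",) + COMPARATOR_METHODS:
            raise ValidationError(f"unknown score_method {self.score_method!r}")
        self.output_dir = Path(self.output_dir)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir)
        d["cv"]["svm_costs"] = list(self.cv.svm_costs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        hp = d.get("hyperparams", {})
        cv = dict(d.get("cv", {}))
        if "svm_costs" in cv:
            cv["svm_costs"] = tuple(cv["svm_costs"])
        return cls(
            hyperparams=HyperParams(**hp) if not isinstance(hp, HyperParams) else hp,
            r=d.get("r", 0.3),
            score_method=d.get("score_method", "pagerank"),
            cv=CVConfig(**cv) if not isinstance(cv, CVConfig) else cv,
            output_dir=Path(d.get("output_dir", "unibrainnet_run")),
            log_level=d.get("log_level", "INFO"),
            standardize=d.get("standardize", True),
            align=d.get("align", True),
            relative_threshold=d.get("relative_threshold", True),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
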