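"""Run configuration: validated settings, YAML/JSON loading."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import NichecastError
from .features import FEATURE_CLASSES


@dataclass
class RunConfig:
    """Settings for a full pipeline run."""

    rm_values: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0])
    feature_combinations: list[str] = field(default_factory=lambda: ["L", "LQ", "LQP"])
    n_replicates: int = 10
    test_fraction: float = 0.25
    background_size: int = 10_000
    seed: int = 0
    class_breaks: tuple[float, float] = (0.33, 0.66)
    correlation_threshold: float = 0.85
    reestimate_threshold_per_scenario: bool = False

    def __post_init__(self):
        if not self.rm_values or any(rm <= 0 for rm in self.rm_values):
            raise NichecastError("rm_values must be non-empty and all > 0")
        for fc in self.feature_combinations:
            if not fc or set(fc) - set(FEATURE_CLASSES):
                raise NichecastError(f"bad feature combination {fc!r}")
        if not (0.0 < self.test_fraction < 1.0):
            raise NichecastError("test_fraction must lie in (0, 1)")
        lo, hi = self.class_breaks
        if not (0.0 < lo < hi < 1.0):
            raise NichecastError("class_breaks must be strictly increasing within (0,1)")
        if self.n_replicates < 1 or self.background_size < 1:
            raise NichecastError("n_replicates and background_size must be >= 1")
        self.class_breaks = (float(lo), float(hi))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_breaks"] = list(self.class_breaks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "class_breaks" in d:
            d["class_breaks"] = tuple(d["class_breaks"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        text = open(path, "r", encoding="utf-8").read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if str(path).endswith(".json"):
                json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
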