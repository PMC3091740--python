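"""Pipeline configuration: one place for every tunable threshold."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from estmir.enrichment import DEFAULT_THRESHOLDS, POINT_MASS, TAIL


@dataclass
class PipelineConfig:
    """Defaults follow the published screening parameters: up to 3 scan
    mismatches, binomial point-mass statistic at thresholds
    0.05/0.01/0.005/0.001, MFEI > 0.85, up to 4 duplex mismatches, 13-nt
    pri-extension flanks, variant support >= 2."""

    max_mm: int = 3
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    statistic_mode: str = POINT_MASS
    mfei_min: float = 0.85
    max_star_mm: int = 4
    max_bulges: int = 2
    max_bulge_size: int = 3
    flank: int = 13
    fold_window: int = 250
    min_support: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.statistic_mode not in (POINT_MASS, TAIL):
            raise ValueError(f"unknown statistic mode {self.statistic_mode!r}")
        if any(not (0 < t <= 1) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.max_mm < 0 or self.min_support < 1:
            raise ValueError("max_mm must be >= 0 and min_support >= 1")
        self.thresholds = tuple(self.thresholds)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return yaml.safe_dump(d, sort_keys=False)
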