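"""Run configuration for the full agreement pipeline.

The YAML surface mirrors :class:`AnalysisConfig` field for field::

    min_usable_seconds: 30
    outlier_sd_multiplier: 3.0
    outlier_sided: upper        # or two_sided
    outlier_streams: [ref]      # any of ref, test
    n_boot: 10000
    seed: 0
    weighting: epoch            # or subject (mean difference weighting)
    loa_multiplier: 1.96
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .screening import ScreeningConfig


@dataclass
class AnalysisConfig:
    min_usable_seconds: int = 30
    outlier_sd_multiplier: float = 3.0
    outlier_sided: str = "upper"
    outlier_streams: tuple[str, ...] = ("ref",)
    n_boot: int = 10_000
    seed: int = 0
    weighting: str = "epoch"
    loa_multiplier: float = 1.96

    def __post_init__(self) -> None:
        self.outlier_streams = tuple(self.outlier_streams)
        if self.weighting not in ("epoch", "subject"):
            raise ValueError("weighting must be 'epoch' or 'subject'")
        if self.loa_multiplier <= 0:
            raise ValueError("loa_multiplier must be positive")
        if self.n_boot < 0:
            raise ValueError("n_boot must be nonnegative")
        self.screening  # validate screening fields eagerly

    @property
    def screening(self) -> ScreeningConfig:
        return ScreeningConfig(
            min_usable_seconds=self.min_usable_seconds,
            outlier_sd_multiplier=self.outlier_sd_multiplier,
            outlier_sided=self.outlier_sided,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outlier_streams"] = list(self.outlier_streams)
        return d
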