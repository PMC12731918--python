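"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .agreement import LOA_MULTIPLIER
from .errors import ConfigError
from .quantify import StatRegion, ThresholdPolicy


@dataclass
class PipelineConfig:
    """Every knob the CLI exposes, with documented defaults.

    threshold_k / threshold_stat_region / threshold_apply_to_sat: the
    slice-level adaptive threshold policy (T = mu + k*sigma, keep >= T).
    dice_pooled: pool Dice counts over the volume (vs slice-averaged).
    icc_variant: fixed to ICC(2,1) absolute agreement; recorded for output.
    loa_multiplier: limits-of-agreement multiplier (1.96).
    """

    threshold_k: float = 0.0
    threshold_stat_region: str = StatRegion.INT_REGION.value
    threshold_apply_to_sat: bool = True
    dice_pooled: bool = True
    icc_variant: str = "ICC(2,1)"
    loa_multiplier: float = LOA_MULTIPLIER
    seed: int = 0

    def __post_init__(self) -> None:
        try:
            StatRegion(self.threshold_stat_region)
        except ValueError as e:
            raise ConfigError(f"unknown stat_region {self.threshold_stat_region!r}") from e
        if not self.loa_multiplier > 0:
            raise ConfigError("loa_multiplier must be positive")

    @property
    def threshold_policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(
            k=self.threshold_k,
            stat_region=StatRegion(self.threshold_stat_region),
            apply_to_sat=self.threshold_apply_to_sat,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)
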