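"""Study-level configuration: generator, scoring and evaluation settings
under one seed, round-tripping losslessly through YAML."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import CUTOFF_AD_VS_NC, CUTOFF_MCI_CONVERSION
from .palz import ScoringOptions
from .synthetic import SimStudyConfig

__all__ = ["StudyConfig"]


@dataclass
class StudyConfig:
    """Everything that defines one end-to-end simulation study.

    One seed (``sim.seed``) governs the whole run; the driver fans it out
    to named substreams so each stage is independently reproducible.
    """

    sim: SimStudyConfig = field(default_factory=SimStudyConfig)
    scoring: ScoringOptions = field(default_factory=ScoringOptions)
    cutoff_ad_vs_nc: float = CUTOFF_AD_VS_NC
    cutoff_mci_conversion: float = CUTOFF_MCI_CONVERSION
    save_volumes: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        self.sim.validate()
        if self.cutoff_ad_vs_nc <= 0 or self.cutoff_mci_conversion <= 0:
            raise ValueError("cutoffs must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "scoring": {
                "smoothing_fwhm_mm": self.scoring.smoothing_fwhm_mm,
                "t_denominator": self.scoring.t_denominator,
                "clip_negative_t": self.scoring.clip_negative_t,
                "pet_score_denominator": self.scoring.pet_score_denominator,
            },
            "cutoff_ad_vs_nc": self.cutoff_ad_vs_nc,
            "cutoff_mci_conversion": self.cutoff_mci_conversion,
            "save_volumes": self.save_volumes,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        sim = SimStudyConfig.from_dict(d.pop("sim", {}))
        scoring = ScoringOptions(**d.pop("scoring", {}))
        return cls(sim=sim, scoring=scoring, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
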