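"""Run configuration: bands, response model, thresholds, seed.

A :class:`RunConfig` captures everything a pipeline run needs to be
reproduced.  It round-trips through YAML (``load(save(c)) == c``) and
every CLI command that produces artifacts writes its resolved config
beside the outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .spectral import BandPair, TemperatureResponseModel

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    band: BandPair = field(default_factory=BandPair)
    response_model: TemperatureResponseModel = field(
        default_factory=lambda: TemperatureResponseModel.linear(
            reference_temp_degC=37.0, reference_ratio=1.7, slope_per_degC=0.062
        )
    )
    z_tolerance_um: float = 0.25
    resolution_confidence: float = 0.95
    diameter_policy: str = "mean_pm_sd"
    diameter_lower_um: float | None = None
    diameter_upper_um: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = asdict(self.band)
        d["response_model"] = {
            k: v for k, v in asdict(self.response_model).items() if v is not None
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = BandPair(**d["band"])
        if "response_model" in d:
            d["response_model"] = TemperatureResponseModel(**d["response_model"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
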