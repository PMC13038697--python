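"""Run configuration: extraction + calibration settings with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .lung_extraction import ExtractionConfig
from .tissue_model import ATELECTASIS_TISSUE_HU, DEFAULT_MEASURED_AIR_HU

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for a measurement run (serialisable round-trip)."""

    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    air_hu: float = DEFAULT_MEASURED_AIR_HU
    tissue_hu: float = ATELECTASIS_TISSUE_HU
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extraction"]["addback_window"] = list(self.extraction.addback_window)
        d["extraction"]["final_window"] = list(self.extraction.final_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ext = dict(d.pop("extraction", {}))
        for key in ("addback_window", "final_window"):
            if key in ext:
                ext[key] = tuple(ext[key])
        return cls(extraction=ExtractionConfig(**ext), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
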