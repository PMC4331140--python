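"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .synthetic import CorruptionProfile, GeneratorParams

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Everything one reproducible pipeline run needs.

    All stage seeds are derived from ``seed``; no stage consults the
    wall clock."""

    output_dir: Path
    codelist_path: Path | None = None
    rules_path: Path | None = None
    generator: GeneratorParams = Field(default_factory=GeneratorParams)
    corruption_a: CorruptionProfile = Field(default_factory=CorruptionProfile)
    corruption_b: CorruptionProfile = Field(default_factory=CorruptionProfile)
    source_a: str = "A"
    source_b: str = "B"
    condition_concept: str = "copd_dx"
    seed: int = 0
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for label, p in (("codelist_path", self.codelist_path),
                         ("rules_path", self.rules_path)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p} does not exist")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    cfg.validate_paths()
    return cfg
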