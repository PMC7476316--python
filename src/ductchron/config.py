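"""Run configuration: YAML config file with CLI-flag overrides.

The pipeline's user-defined variables — paths, core width, year bounds,
combine flag, QC bands — can live in a small YAML file so a build is
reproducible from one artifact; any flag given on the command line wins
over the file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .chronology import QCRules
from .errors import ValidationError


@dataclass
class RunConfig:
    duct_dir: str | None = None
    rwl: str | None = None
    out: str | None = None
    core_width: float | None = None
    first_year: int | None = None
    last_year: int | None = None
    combine: bool = False
    duct_size_min_mm2: float = QCRules.duct_size_min_mm2
    duct_size_max_mm2: float = QCRules.duct_size_max_mm2
    relative_area_max_pct: float = QCRules.relative_area_max_pct
    seed: int | None = None

    def validate(self) -> None:
        if (
            self.first_year is not None
            and self.last_year is not None
            and self.first_year > self.last_year
        ):
            raise ValidationError(
                f"first_year {self.first_year} after last_year {self.last_year}"
            )
        if self.core_width is not None and self.core_width <= 0:
            raise ValidationError("core_width must be positive")

    def qc_rules(self) -> QCRules:
        return QCRules(
            duct_size_min_mm2=self.duct_size_min_mm2,
            duct_size_max_mm2=self.duct_size_max_mm2,
            relative_area_max_pct=self.relative_area_max_pct,
        )


def load_config(path: str | Path | None, overrides: dict) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    ``overrides`` entries that are ``None`` (flag not given) are ignored.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must be a mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**values)
    cfg.validate()
    return cfg
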