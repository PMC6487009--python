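"""Pipeline configuration: HU windows, cutoffs, endpoints, seed.

Defaults are the protocol's published values: adipose −190…−30 HU,
muscle −30…150 HU, 3 mm duct and 12 mm parenchyma cutoffs, endpoints
Clavien-Dindo ≥ IIIb and ISGPF grade B/C, 95% Wald intervals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .composition import SarcopeniaThresholds
from .phantom import DEFAULT_SEED
from .segmentation import TissueRange, adipose_range, muscle_range


class ConfigError(ValueError):
    pass


_SCHEMA: dict[str, type] = {
    "adipose_low": (int, float), "adipose_high": (int, float),
    "adipose_rule": str, "muscle_low": (int, float), "muscle_high": (int, float),
    "muscle_rule": str, "duct_cutoff_mm": (int, float),
    "parenchyma_cutoff_mm": (int, float), "major_complication_grade": str,
    "severe_popf_grades": list, "ci_level": (int, float), "percent_mode": str,
    "seed": int, "output_dir": str, "sarcopenia": dict,
}


@dataclass(frozen=True)
class PipelineConfig:
    adipose_low: float = -190.0
    adipose_high: float = -30.0
    adipose_rule: str = "[]"
    muscle_low: float = -30.0
    muscle_high: float = 150.0
    muscle_rule: str = "(]"
    duct_cutoff_mm: float = 3.0
    parenchyma_cutoff_mm: float = 12.0
    major_complication_grade: str = "IIIb"
    severe_popf_grades: tuple = ("B", "C")
    ci_level: float = 0.95
    percent_mode: str = "half-up"
    seed: int = DEFAULT_SEED
    output_dir: str = "."
    sarcopenia: SarcopeniaThresholds = field(default_factory=SarcopeniaThresholds)

    def __post_init__(self):
        if not 0.5 < self.ci_level < 1.0:
            raise ConfigError("ci_level must lie in (0.5, 1)")
        if self.duct_cutoff_mm <= 0 or self.parenchyma_cutoff_mm <= 0:
            raise ConfigError("cutoffs must be > 0")
        # reuse TissueRange validation for the windows
        self.adipose()
        self.muscle()

    def adipose(self) -> TissueRange:
        return TissueRange("adipose", self.adipose_low, self.adipose_high,
                           self.adipose_rule)

    def muscle(self) -> TissueRange:
        return TissueRange("muscle", self.muscle_low, self.muscle_high,
                           self.muscle_rule)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["severe_popf_grades"] = list(self.severe_popf_grades)
        return d

    def hash(self) -> str:
        """Short stable digest embedded in every output file header."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:8]


def default_config() -> PipelineConfig:
    return PipelineConfig()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config, validating keys and types against the schema."""
    if path is None:
        return default_config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for k, v in raw.items():
        if not isinstance(v, _SCHEMA[k]):
            raise ConfigError(f"config key {k!r} has wrong type {type(v).__name__}")
    sarc = raw.pop("sarcopenia", None)
    if "severe_popf_grades" in raw:
        raw["severe_popf_grades"] = tuple(raw["severe_popf_grades"])
    kw = dict(raw)
    if sarc is not None:
        kw["sarcopenia"] = SarcopeniaThresholds(**sarc)
    return PipelineConfig(**kw)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=True))
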