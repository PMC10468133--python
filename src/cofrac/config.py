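"""Validated pipeline configuration (YAML-backed, CLI-overridable)."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import InputError

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Thresholds, windows, dialects, seeds and paths for a pipeline run."""

    # score thresholds (all strictly-greater-than cuts)
    pcc_threshold: float = 0.85
    spearman_threshold: float = 0.85
    prince_threshold: float = 0.85
    enrichment_alpha: float = 0.01
    min_correspondence: float = 0.5
    # structure
    half_window: int = 2
    fraction_range: tuple[int, int] = (23, 50)
    min_unique_peptides: int = 3
    n_groups: int = 10
    k_range: tuple[int, int] = (1, 12)
    min_clique_size: int = 2
    # randomness
    seed: int = 17
    # inputs (any may be None; stages needing them then fail validation)
    trace_csv: str | None = None
    protein_groups_tsv: str | None = None
    reference_list: str | None = None
    reference_complexes_tsv: str | None = None
    annotation_tsv: str | None = None

    def validate(self) -> "PipelineConfig":
        for name in ("pcc_threshold", "spearman_threshold", "prince_threshold",
                     "enrichment_alpha", "min_correspondence"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InputError(f"{name}={v} must lie in (0, 1)")
        if self.half_window < 1:
            raise InputError("half_window must be >= 1")
        if self.fraction_range[0] >= self.fraction_range[1]:
            raise InputError("fraction_range must be increasing")
        if self.k_range[0] < 1 or self.k_range[0] > self.k_range[1]:
            raise InputError("k_range must satisfy 1 <= k_min <= k_max")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        d["fraction_range"] = list(self.fraction_range)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise InputError(f"unsupported config schema version {version}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fraction_range", "k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
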