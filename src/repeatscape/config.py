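"""Pipeline configuration: serialized YAML config with strict key checking.

Precedence is CLI flag > config file > dataclass default.  Unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


def _from_mapping(cls, data: dict[str, Any], context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateStageConfig:
    enabled: bool = True
    n_pairs: int = 6
    depth_mean: float = 30.0
    tumor_variance_inflation: float = 4.0
    breakpoint_jitter_sd: float = 100.0
    n_sv: int = 200
    catalog_size: int = 5000
    n_signatures: int = 5


@dataclass
class SvStageConfig:
    enabled: bool = True
    tol: int = 500
    min_size: int = 50
    min_support: int = 2


@dataclass
class SignatureStageConfig:
    enabled: bool = True
    signature_matrix: str | None = None  # path; default: the simulated matrix


@dataclass
class CoverageStageConfig:
    enabled: bool = True
    bin_width: int = 1000
    partial: str = "merge"  # partial-bin dialect: merge | keep
    levene_center: str = "mean"


@dataclass
class MethylationStageConfig:
    enabled: bool = True
    classes: tuple[str, ...] = ("active_hor", "inactive_hor")
    hrd_cutoff: int = 63
    method: str = "pooled"
    n_components: int = 2


@dataclass
class ThorStageConfig:
    enabled: bool = True
    window: int = 100
    hyper_threshold: float = 0.6
    hypo_threshold: float = 0.3
    thor_region: str | None = None  # "chrom:start-end"; default: simulated span


@dataclass
class PipelineConfig:
    outdir: str = "repeatscape_out"
    seed: int = 0
    simulate: SimulateStageConfig = field(default_factory=SimulateStageConfig)
    sv: SvStageConfig = field(default_factory=SvStageConfig)
    signatures: SignatureStageConfig = field(default_factory=SignatureStageConfig)
    coverage: CoverageStageConfig = field(default_factory=CoverageStageConfig)
    methylation: MethylationStageConfig = field(default_factory=MethylationStageConfig)
    thor: ThorStageConfig = field(default_factory=ThorStageConfig)

    _SECTIONS = {
        "simulate": SimulateStageConfig,
        "sv": SvStageConfig,
        "signatures": SignatureStageConfig,
        "coverage": CoverageStageConfig,
        "methylation": MethylationStageConfig,
        "thor": ThorStageConfig,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                section = data.pop(name)
                if not isinstance(section, dict):
                    raise ValueError(f"config section {name!r} must be a mapping")
                kwargs[name] = _from_mapping(section_cls, section, f"section {name!r}")
        top_known = {"outdir", "seed"}
        unknown = set(data) - top_known
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    def validate(self) -> None:
        if self.coverage.partial not in {"merge", "keep"}:
            raise ValueError("coverage.partial must be merge|keep")
        if self.methylation.method not in {"pooled", "mean_of_sites"}:
            raise ValueError("methylation.method must be pooled|mean_of_sites")
        if not self.simulate.enabled:
            # without the generator, every stage needs externally provided
            # inputs under outdir/inputs (written by a previous run)
            inputs = Path(self.outdir) / "inputs"
            if not inputs.is_dir():
                raise ValueError(
                    f"simulate stage disabled but no inputs directory at {inputs}"
                )
        if self.signatures.signature_matrix is not None:
            if not Path(self.signatures.signature_matrix).is_file():
                raise ValueError(
                    f"signature matrix not found: {self.signatures.signature_matrix}"
                )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        data = self.to_dict()
        data.pop("outdir", None)  # hash analysis parameters, not the destination
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
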