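"""Pipeline configuration: a single YAML file with schema validation and
exhaustive defaults.  Every paper-silent threshold lives here."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import yaml

from .qpcr import DEFAULT_RATIO_CUTOFF
from .segmentation import SegmentationParams
from .simulate import EventSpec, SimulationConfig


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-domain parameter values."""


def _build(cls, section: Mapping[str, Any], where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where} configuration: {exc}") from exc


@dataclass(frozen=True)
class SummarizeConfig:
    bin_size: int = 1_000_000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")


@dataclass(frozen=True)
class QPCRConfig:
    cutoff: float = DEFAULT_RATIO_CUTOFF

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    outdir: Path = Path("lincnv_out")
    #: GC correction applied per sample before pairing (configurable order)
    gc_correction: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    calling: SegmentationParams = field(default_factory=SegmentationParams)
    summarize: SummarizeConfig = field(default_factory=SummarizeConfig)
    qpcr: QPCRConfig = field(default_factory=QPCRConfig)

    @staticmethod
    def from_dict(data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        top_known = {"outdir", "gc_correction", "simulation", "calling", "summarize", "qpcr"}
        unknown = set(data) - top_known
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        sim = dict(data.get("simulation", {}) or {})
        if "events" in sim and sim["events"] is not None:
            sim["events"] = tuple(
                _build(EventSpec, ev, "simulation.events[]") for ev in sim["events"]
            )
        if "chrom_lengths" in sim:
            sim["chrom_lengths"] = {str(k): int(v) for k, v in sim["chrom_lengths"].items()}
        return PipelineConfig(
            outdir=Path(data.get("outdir", "lincnv_out")),
            gc_correction=bool(data.get("gc_correction", True)),
            simulation=_build(SimulationConfig, sim, "simulation"),
            calling=_build(SegmentationParams, dict(data.get("calling", {}) or {}), "calling"),
            summarize=_build(SummarizeConfig, dict(data.get("summarize", {}) or {}), "summarize"),
            qpcr=_build(QPCRConfig, dict(data.get("qpcr", {}) or {}), "qpcr"),
        )

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return PipelineConfig.from_dict(data or {})

    def with_overrides(self, outdir=None, seed=None) -> "PipelineConfig":
        cfg = self
        if outdir is not None:
            cfg = dataclasses.replace(cfg, outdir=Path(outdir))
        if seed is not None:
            cfg = dataclasses.replace(
                cfg, simulation=dataclasses.replace(cfg.simulation, seed=int(seed))
            )
        return cfg
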