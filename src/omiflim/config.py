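"""Run configuration: every tunable parameter of every stage, with defaults,
loadable from YAML or JSON. Unknown keys are rejected with the offending
key named."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import CohortDesign

__all__ = ["RunConfig", "StatsOutcome", "load_config"]

_TUPLE_FIELDS = {"treatments", "field_shape", "radius_range", "shape", "tnfa_labels"}


def _build(cls, d: dict, path: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(d, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    for key in d:
        if key not in names:
            raise ValueError(f"unknown config key {path}.{key}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in d.items()
    }
    return cls(**kwargs)


@dataclass(frozen=True)
class FitStageConfig:
    n_bins: int = 256
    window_ns: float = 12.5
    irf_fwhm_ps: float = 260.0
    irf_peak_bin: int = 25
    threshold: float = 500.0
    binning: int = 1
    objective: str = "wls"


@dataclass(frozen=True)
class SegmentStageConfig:
    threshold: float = 0.15
    min_area: int = 25
    gfp_threshold: float | None = None
    bacteria_threshold: float | None = None


@dataclass(frozen=True)
class ReporterConfig:
    signal: float = 1000.0
    background: float = 10.0
    noise_sd: float = 2.0


@dataclass(frozen=True)
class StatsOutcome:
    outcome: str
    log_transform: bool = False


@dataclass(frozen=True)
class StatsStageConfig:
    outcomes: tuple = (
        StatsOutcome("orr", log_transform=True),
        StatsOutcome("nadph_tm", log_transform=True),
        StatsOutcome("omi"),
    )
    treatment: str = "treatment"
    block: str = "day_id"
    cluster: str = "larva_id"
    interaction: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for ``run-all``."""

    seed: int = 0
    simulate: CohortDesign = field(default_factory=CohortDesign)
    fit: FitStageConfig = field(default_factory=FitStageConfig)
    segment: SegmentStageConfig = field(default_factory=SegmentStageConfig)
    reporter: ReporterConfig = field(default_factory=ReporterConfig)
    stats: StatsStageConfig = field(default_factory=StatsStageConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        known = {f.name for f in dataclasses.fields(cls)}
        for key in d:
            if key not in known:
                raise ValueError(f"unknown config key {key}")
        kwargs: dict = {}
        if "seed" in d:
            kwargs["seed"] = int(d.pop("seed"))
        section_types = {
            "simulate": CohortDesign,
            "fit": FitStageConfig,
            "segment": SegmentStageConfig,
            "reporter": ReporterConfig,
        }
        for name, typ in section_types.items():
            if name in d:
                kwargs[name] = _build(typ, d.pop(name), name)
        if "stats" in d:
            sd = dict(d.pop("stats"))
            if "outcomes" in sd:
                sd["outcomes"] = tuple(
                    _build(StatsOutcome, o, "stats.outcomes") for o in sd["outcomes"]
                )
            kwargs["stats"] = _build(StatsStageConfig, sd, "stats")
        cfg = cls(**kwargs)
        # propagate the master seed into the simulation design unless the
        # design pins its own
        if "seed" in kwargs and cfg.simulate.seed == 0 and cfg.seed != 0:
            cfg = dataclasses.replace(
                cfg, simulate=dataclasses.replace(cfg.simulate, seed=cfg.seed)
            )
        return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.from_dict(data or {})
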