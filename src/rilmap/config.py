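"""Pipeline configuration: every tunable default in one serializable record."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class SimConfig:
    n_chromosomes: int = 12
    chrom_length_cM: float = 110.0
    n_rils: int = 119
    final_generation: int = 8
    markers_per_chrom: int = 50
    translocation: tuple[int, int, float, float] | None = None
    polymorphic_fraction: float = 1.0
    miss_rate: float = 0.025
    error_rate: float = 1e-4


@dataclass
class CallConfig:
    min_sppdev: float = 1.1
    max_missing: float = 0.10
    min_probes: int = 2
    min_span: int = 2
    max_allele_freq: float = 0.90
    min_separation: float = 3.3
    dead_zone: float = 0.25
    cultivated: str = "P_A"
    wild: str = "P_B"


@dataclass
class GroupConfig:
    max_r: float = 0.3
    min_lod: float = 5.0
    min_informative: int = 2
    break_r: float = 0.35
    link_r: float = 0.25
    max_linking_fraction: float = 0.10


@dataclass
class MapConfig:
    mapping_function: str = "haldane"
    generation: int | None = None  # exact finite-generation RIL correction
    n_restarts: int = 10
    window_max: int = 5
    max_gap_cM: float = 30.0
    window_cM: float = 5.0
    min_windows: int = 2
    miss_thresh: float = 0.4
    min_crossovers: int = 2
    split_threshold: float = 0.2
    alpha_distortion: float = 0.01


@dataclass
class PipelineConfig:
    """All stage parameters plus the mandatory master seed."""

    seed: int = 1
    sim: SimConfig = field(default_factory=SimConfig)
    call: CallConfig = field(default_factory=CallConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    map: MapConfig = field(default_factory=MapConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        kwargs = {}
        for name, sub in (("sim", SimConfig), ("call", CallConfig),
                          ("group", GroupConfig), ("map", MapConfig)):
            if name in raw:
                d = dict(raw[name])
                if name == "sim" and d.get("translocation") is not None:
                    d["translocation"] = tuple(d["translocation"])
                kwargs[name] = sub(**d)
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)
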