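"""Pipeline configuration: validated parameters with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .nbs import DEFAULT_F_THRESHOLD
from .paradigm import ParadigmSpec
from .preprocessing import (
    MIN_TRIALS_PER_CONDITION,
    MOTION_THRESHOLD_MM,
    BandSpec,
    CANONICAL_BANDS,
)
from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline end to end.

    Statistical defaults follow the study: AEC component-forming
    thresholds t = 2.75 / 3.0 / 3.5, wPLI t = 3.0, interaction F = 7,
    5000 permutations, alpha 0.05 Bonferroni-corrected within metric.
    ``response_disagreement_rate`` is the probability that a subject's
    in-scanner familiarity rating flips the pre-selected stimulus label.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    epoch_s: float = 10.0
    edge_trim_s: float = 1.0
    motion_threshold_mm: float = MOTION_THRESHOLD_MM
    min_trials: int = MIN_TRIALS_PER_CONDITION
    metrics: tuple[str, ...] = ("aec", "wpli")
    modes: tuple[str, ...] = ("roi", "whole_brain")
    aec_thresholds: tuple[float, ...] = (2.75, 3.0, 3.5)
    wpli_threshold: float = 3.0
    interaction_f: float = DEFAULT_F_THRESHOLD
    n_permutations: int = 5000
    alpha: float = 0.05
    response_disagreement_rate: float = 0.1
    sensor_space: bool = False
    node_table_path: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.metrics = tuple(self.metrics)
        self.modes = tuple(self.modes)
        self.aec_thresholds = tuple(self.aec_thresholds)
        for m in self.metrics:
            if m not in ("aec", "wpli"):
                raise ValueError(f"unknown metric {m!r}")
        for mode in self.modes:
            if mode not in ("roi", "whole_brain"):
                raise ValueError(f"unknown mode {mode!r}")
        if self.epoch_s <= 0 or self.edge_trim_s < 0:
            raise ValueError("epoch_s must be positive, edge_trim_s non-negative")
        if 2 * self.edge_trim_s >= self.epoch_s:
            raise ValueError("edge trim longer than the epoch")
        if self.n_permutations < 1 or not 0 < self.alpha < 1:
            raise ValueError("invalid permutation count or alpha")
        if min(self.aec_thresholds) <= 0 or self.wpli_threshold <= 0 or self.interaction_f <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_trials < 1 or self.motion_threshold_mm <= 0:
            raise ValueError("invalid QC settings")
        if self.paradigm.sampling_rate_hz != self.simulation.sampling_rate_hz:
            raise ValueError("paradigm and simulation sampling rates disagree")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        sim = d["simulation"]
        sim["bands"] = [list(b) for b in self.simulation.bands]
        sim["planted_edges"] = [
            {
                "band": band,
                "metric": metric,
                "group": group,
                "condition": condition,
                "edges": [list(e) for e in edges],
            }
            for (band, metric, group, condition), edges in self.simulation.planted_edges.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "bands" in sim:
            sim["bands"] = tuple(BandSpec(str(b[0]), float(b[1]), float(b[2])) for b in sim["bands"])
        else:
            sim["bands"] = CANONICAL_BANDS
        planted = {}
        for item in sim.pop("planted_edges", []) or []:
            key = (item["band"], item["metric"], item["group"], item["condition"])
            planted[key] = [tuple(e) for e in item["edges"]]
        sim["planted_edges"] = planted
        par = dict(d.pop("paradigm", {}))
        return cls(
            simulation=SimulationConfig(**sim),
            paradigm=ParadigmSpec(**par),
            **d,
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))
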