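"""Run configuration for the pipeline.

A single YAML file (or keyword overrides) carries every stage's parameters
plus one global seed; independent per-stage random streams are spawned from
the global seed so stages can be rerun in isolation and still reproduce.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .demography import DemographicModel

#: order of the pipeline stages
STAGES = ("simulate", "extract", "conflate", "fit_ages", "mu_bias")


@dataclass
class RunConfig:
    # demography: list of [start_time, size, growth_rate] epochs
    epochs: list = field(
        default_factory=lambda: [
            [0.0, 4.0e6, 0.017],
            [368.0, 7.7e3, 0.0],
            [3.5e3, 2.45e4, 0.0],
            [1.7e4, 1.25e4, 0.0],
        ]
    )
    region_length_bp: int = 20_000_000
    n_haplotypes: int = 2000
    mu: float = 1.2e-8
    recomb: float = 1e-8
    n_regions: int = 1
    # extraction
    grid_step_cm: float = 0.01
    max_age_gen: float = 3000.0
    min_length_cm: float = 0.2
    # conflation
    w_cm: float = 0.2
    max_gap_cm: float = 0.0
    min_combined_cm: float = 1.0
    bin_width_cm: float = 0.1
    # age model
    em_tol: float = 1e-6
    em_max_iter: int = 500
    em_restarts: int = 5
    min_bin_count: int = 50
    # mutation-rate experiment
    n_sets: int = 1000
    set_size: int = 5000
    # array down-sampling
    array_density: int = 5800
    array_maf_min: float = 0.05
    # global
    seed: int = 1
    stages: list = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError("stages must be listed in pipeline order")

    def model(self) -> DemographicModel:
        return DemographicModel(epochs=tuple(tuple(e) for e in self.epochs))

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic per-stage (and per-region) seed below 2**31."""
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage), index])
        return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31 - 1)) + 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        array = data.pop("array", None)
        if array:
            data.setdefault("array_density", array.get("density", 5800))
            data.setdefault("array_maf_min", array.get("maf_min", 0.05))
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
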