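"""Run configuration for the simulation/evaluation pipeline.

A run is fully described by a small YAML file, e.g.::

    grid:
      trend: [-0.1, 0.0, 0.1]
      initial_abundance: [5, 20, 100]
      n_years: [10, 20]
      n_surveys: [3, 5]
      detection_prob: [0.1, 0.3, 0.5, 0.7]
    n_reps: 100
    base_seed: 1
    with_gof: false
    n_boot: 200
    n_jobs: 1
    output_dir: results

Omitted grid keys default to the canonical value sets, so an empty file
reproduces the full 144-scenario design at 100 replicates per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import PAPER_GRID_VALUES, build_grid
from .simulator import ScenarioSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    trend: list[float] = field(
        default_factory=lambda: list(PAPER_GRID_VALUES["trend"]))
    initial_abundance: list[int] = field(
        default_factory=lambda: list(PAPER_GRID_VALUES["initial_abundance"]))
    n_years: list[int] = field(
        default_factory=lambda: list(PAPER_GRID_VALUES["n_years"]))
    n_surveys: list[int] = field(
        default_factory=lambda: list(PAPER_GRID_VALUES["n_surveys"]))
    detection_prob: list[float] = field(
        default_factory=lambda: list(PAPER_GRID_VALUES["detection_prob"]))
    n_reps: int = 100
    base_seed: int = 0
    with_gof: bool = False
    n_boot: int = 200
    n_jobs: int = 1
    output_dir: str = "results"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("trend", "initial_abundance", "n_years", "n_surveys",
                     "detection_prob"):
            vals = getattr(self, name)
            if not isinstance(vals, (list, tuple)) or len(vals) == 0:
                raise ValueError(f"config field '{name}' must be a non-empty list")
        for p in self.detection_prob:
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"config field 'detection_prob' has invalid value {p}: "
                    "must be strictly between 0 and 1")
        for n0 in self.initial_abundance:
            if n0 < 1:
                raise ValueError(
                    f"config field 'initial_abundance' has invalid value {n0}")
        for ny in self.n_years:
            if ny < 2:
                raise ValueError(f"config field 'n_years' has invalid value {ny}")
        for ns in self.n_surveys:
            if ns < 2:
                raise ValueError(f"config field 'n_surveys' has invalid value {ns}")
        if self.n_reps < 1:
            raise ValueError(f"config field 'n_reps' must be >= 1, got {self.n_reps}")
        if self.with_gof and self.n_boot < 1:
            raise ValueError("config field 'n_boot' must be >= 1 when with_gof")
        if self.n_jobs < 1:
            raise ValueError(f"config field 'n_jobs' must be >= 1, got {self.n_jobs}")

    def grid(self) -> list[ScenarioSpec]:
        return build_grid(
            trend=self.trend, initial_abundance=self.initial_abundance,
            n_years=self.n_years, n_surveys=self.n_surveys,
            detection_prob=self.detection_prob, n_reps=self.n_reps,
            base_seed=self.base_seed)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; ``None`` or an empty file gives defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    grid = raw.pop("grid", {}) or {}
    if not isinstance(grid, dict):
        raise ValueError(f"{path}: 'grid' must be a mapping of value lists")
    known_grid = {"trend", "initial_abundance", "n_years", "n_surveys",
                  "detection_prob"}
    unknown = set(grid) - known_grid
    if unknown:
        raise ValueError(f"{path}: unknown grid fields {sorted(unknown)}")
    known_top = {"n_reps", "base_seed", "with_gof", "n_boot", "n_jobs",
                 "output_dir"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
    return RunConfig(**grid, **raw)
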