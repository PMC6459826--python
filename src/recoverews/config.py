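"""YAML scenario configuration for the simulation experiment.

A config document describes the grid, species parameters, phase years,
plateau fishing mortality, treatment list, replication and seeding.  Two
built-in profiles exist: ``scaled`` (50 replicates, fast converged burn-in;
the desk-scale default) and ``full`` (300 replicates, full 300-year
burn-in, the original design scale).
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import SizeGrid, build_size_grid
from .simulator import DEFAULT_TREATMENTS, SpeciesParams

__all__ = ["ScenarioConfig", "default_config", "load_config", "config_hash"]


@dataclass
class ScenarioConfig:
    grid: dict = field(default_factory=lambda: {
        "n_classes": 100, "w_min": 0.001, "w_max": 4.0e4})
    species: dict = field(default_factory=dict)
    phases: dict = field(default_factory=lambda: {
        "burn_in_start": 1667, "historic_start": 1967,
        "plateau_start": 2010, "release_start": 2040, "end_year": 2200})
    plateau_F: float = 0.6
    treatments: list = field(
        default_factory=lambda: list(DEFAULT_TREATMENTS))
    n_reps: int = 50
    base_seed: int = 0
    burn_in: str = "fast"

    def build_grid(self) -> SizeGrid:
        return build_size_grid(**self.grid)

    def build_params(self) -> SpeciesParams:
        return SpeciesParams(**self.species)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> "ScenarioConfig":
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.burn_in not in ("fast", "full"):
            raise ValueError(f"burn_in must be 'fast' or 'full', "
                             f"got {self.burn_in!r}")
        if not self.treatments:
            raise ValueError("treatment list is empty")
        if any(not (0 <= r <= 1) for r in self.treatments):
            raise ValueError("decline rates must be in [0, 1]")
        if self.plateau_F < 0:
            raise ValueError("plateau_F must be >= 0")
        self.build_grid()
        self.build_params()
        return self


def default_config(profile: str = "scaled") -> ScenarioConfig:
    if profile == "scaled":
        return ScenarioConfig()
    if profile == "full":
        return ScenarioConfig(n_reps=300, burn_in="full")
    raise ValueError(f"unknown profile {profile!r}")


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario config (missing keys take
    defaults)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} is not a YAML mapping")
    base = default_config(doc.pop("profile", "scaled"))
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in doc.items():
        if key in ("grid", "species", "phases"):
            merged = dict(getattr(base, key))
            merged.update(value or {})
            setattr(base, key, merged)
        else:
            setattr(base, key, value)
    return base.validate()


def config_hash(cfg: ScenarioConfig, seed: int | None = None) -> str:
    """Deterministic hash of config + seed (same inputs, same hash)."""
    doc = cfg.to_dict()
    if seed is not None:
        doc["_seed"] = seed
    blob = yaml.safe_dump(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
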