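"""Configuration objects for synthetic cohorts and pipeline runs.

Seeding scheme
--------------
All randomness flows from a single master ``seed``. Each stage draws from
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))`` where the stage
index is fixed by :data:`STAGE_KEYS`. Stages can therefore be regenerated
independently and in any order without perturbing each other.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "RunConfig",
    "stage_rng",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


#: fixed stage -> spawn-key registry (order is part of the contract)
STAGE_KEYS = {
    "training_cohort": 0,
    "training_idps": 1,
    "loadings": 2,  # generative loadings shared by training & longitudinal sets
    "longitudinal_cohort": 3,
    "longitudinal_idps": 4,
    "cognition": 5,
    "crossval": 6,
    "permutation": 7,
    "pipeline": 8,
}


def stage_rng(seed: int, stage: str, extra: Tuple[int, ...] = ()) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    if stage not in STAGE_KEYS:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGE_KEYS)}")
    ss = np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage],) + tuple(extra))
    return np.random.default_rng(ss)


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Units: ages, inter-scan intervals (ISI) and brain-age gaps (BAG) are in
    years; BAG rates in years of BAG per year; cognitive couplings in percent
    change per unit BAG rate.
    """

    n_train: int = 1500
    n_longitudinal: int = 400  # per main group (Pandemic, Control)
    age_mean: float = 62.6
    age_sd: float = 7.6
    age_range: Tuple[float, float] = (45.0, 82.0)
    n_idps: int = 200
    n_signal_components: int = 10
    signal_to_noise: float = 4.0  # sd(age-driven signal) / sd(measurement noise)
    n_confounds: int = 5
    confound_strength: float = 0.5
    # spread of stable individual deviation (true BAG) around chronological age
    bag_sd: float = 3.0
    # stable subject-level variability of signal-component scores (session-invariant)
    component_noise_sd: float = 0.5
    # longitudinal structure
    baseline_drift: float = 0.10          # mean BAG rate in everyone, y/y
    age_drift_slope: float = 0.00821      # extra y/y per year of avg age (~3 d/y)
    rbag_noise_sd: float = 0.70           # between-subject sd of true BAG rate, y/y
    true_rbag_effect: float = 0.458       # Pandemic-vs-Control offset, y/y
    deprivation_interaction: float = 0.2  # extra offset, deprived Pandemic, y/y
    # cognition
    cognition_coupling: float = 10.0      # % change per unit R_BAG, infected only
    cognition_drift: float = 2.0          # mean % change in everyone
    cognition_noise: float = 5.0          # sd of % change noise
    # group composition / timing
    covid_fraction: float = 0.31          # infected share of Pandemic group
    female_fraction: float = 0.55
    isi_range_control: Tuple[float, float] = (2.0, 2.5)
    isi_range_pandemic: Tuple[float, float] = (1.0, 4.5)
    pandemic_onset: str = "2020-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train", "n_longitudinal", "n_idps"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        if self.n_signal_components < 0:
            raise ConfigError("n_signal_components must be >= 0")
        if self.n_signal_components > self.n_idps:
            raise ConfigError("n_signal_components must be <= n_idps")
        if self.n_confounds < 0:
            raise ConfigError("n_confounds must be >= 0")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigError("age_range must satisfy min < max")
        if self.signal_to_noise < 0:
            raise ConfigError("signal_to_noise must be >= 0")
        if self.confound_strength < 0:
            raise ConfigError("confound_strength must be >= 0")
        for name in ("isi_range_control", "isi_range_pandemic"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ConfigError(f"{name} must be positive with min <= max")
        if not 0.0 <= self.covid_fraction <= 1.0:
            raise ConfigError("covid_fraction must be in [0, 1]")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["isi_range_control"] = list(self.isi_range_control)
        d["isi_range_pandemic"] = list(self.isi_range_pandemic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("age_range", "isi_range_control", "isi_range_pandemic"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline settings (simulate -> QC -> fit -> stats)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "runs/synthetic"
    # model hyper-parameters
    k: int = 50
    folds: int = 20
    repeats: int = 100
    bias_basis: str = "quadratic"
    # QC thresholds
    z_threshold: float = 5.0
    isi_lower_pct: float = 10.0
    min_isi_years: float = 2.0
    onset_date: str = "2020-03-01"
    # statistics
    n_perm: int = 5000
    alpha: float = 0.05
    low_pct: float = 30.0
    high_pct: float = 70.0
    # display
    rate_display_unit: str = "months_per_year"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if self.k <= 0:
            raise ConfigError("k must be a positive count")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run field(s): {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path, kind: str = "run") -> "RunConfig | SimulationConfig":
    """Read a config from a YAML or JSON file (YAML is a JSON superset here)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    if kind == "run":
        return RunConfig.from_dict(data)
    if kind == "simulation":
        return SimulationConfig.from_dict(data)
    raise ConfigError(f"unknown config kind {kind!r}")


def config_hash(d: dict) -> str:
    """Stable sha256 of a JSON-serialisable config dict."""
    import hashlib

    payload = json.dumps(d, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(payload).hexdigest()
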