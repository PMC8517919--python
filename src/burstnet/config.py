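"""Run configuration: every stage parameter in one round-trippable object.

The saved config materializes every defaulted value, so a run is fully
described by its file; the SHA-256 hash of the canonical JSON form is
stamped into every output the pipeline writes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import ClassifierConfig
from .containers import WindowSpec
from .hmm import HMMConfig
from .simulate import SimulationConfig, TaskProfile


@dataclass
class ConditioningConfig:
    low_hz: float = 1.0
    high_hz: float = 48.0
    order: int = 4
    target_fs: float = 100.0
    orthogonalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass
class EnvelopeConfig:
    band: tuple[float, float] = (13.0, 30.0)
    cycles: int = 7
    freq_step: float = 1.0


@dataclass
class StatsConfig:
    q: float = 0.05


@dataclass
class RunConfig:
    """Full pipeline configuration (simulation through classification)."""

    seed: int = 0
    workflow: str = "resting"            # "resting" or "task"
    n_per_group: int = 6
    n_trials: int = 40                   # task workflow only
    burst_threshold: float = 2.0 / 3.0
    motor_regions: tuple[str, str] = ("Precentral_L", "Precentral_R")
    run_classification: bool = False
    n_permutations: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    conditioning: ConditioningConfig = field(default_factory=ConditioningConfig)
    hmm: HMMConfig = field(default_factory=HMMConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    windows: WindowSpec = field(default_factory=WindowSpec)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        if self.workflow not in ("resting", "task"):
            raise ValueError("workflow must be 'resting' or 'task'")
        if not 0 < self.burst_threshold < 1:
            raise ValueError("burst_threshold must lie in (0, 1)")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        sim = d["simulation"]
        C = sim["coincidence_matrix"]
        sim["coincidence_matrix"] = (None if C is None
                                     else np.asarray(C).tolist())
        sim["task_profile"] = dict(
            windows=[list(w) for w in self.simulation.task_profile.windows],
            baseline=self.simulation.task_profile.baseline)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if sim.get("coincidence_matrix") is not None:
            sim["coincidence_matrix"] = np.asarray(sim["coincidence_matrix"])
        if isinstance(sim.get("task_profile"), dict):
            tp = sim["task_profile"]
            sim["task_profile"] = TaskProfile(
                windows=[tuple(w) for w in tp["windows"]],
                baseline=tp.get("baseline", 1.0))
        sim["carrier_band"] = tuple(sim.get("carrier_band", (13.0, 30.0)))
        kwargs = dict(
            simulation=SimulationConfig(**sim),
            conditioning=ConditioningConfig(**d.pop("conditioning", {})),
            hmm=HMMConfig(**d.pop("hmm", {})),
            envelope=EnvelopeConfig(**{
                k: tuple(v) if k == "band" else v
                for k, v in d.pop("envelope", {}).items()}),
            windows=WindowSpec(**{k: tuple(v) for k, v in
                                  d.pop("windows", {}).items()}),
            stats=StatsConfig(**d.pop("stats", {})),
            classifier=ClassifierConfig(**d.pop("classifier", {})),
        )
        if "motor_regions" in d:
            d["motor_regions"] = tuple(d["motor_regions"])
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
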