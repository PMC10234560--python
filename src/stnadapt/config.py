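"""YAML analysis configuration and run manifests.

The configuration mirrors the generator and analysis dataclasses; every
random choice is controlled by explicit seeds so a run is reproducible from
the file alone.  The manifest records a hash of the resolved configuration,
the package version, per-stage wall time, and the full output inventory,
and is written atomically at the end of a run.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import AgentConfig, LfpGenConfig, StimBehaviorEffect
from .schedule import StimScheduleConfig
from .task import TaskConfig

__all__ = ["AnalysisConfig", "RunManifest", "load_config"]


@dataclass
class AnalysisConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentConfig = field(default_factory=AgentConfig)
    lfp: LfpGenConfig = field(default_factory=LfpGenConfig)
    stim: StimScheduleConfig | None = None
    stim_effect: StimBehaviorEffect | None = None
    n_subjects: int = 16
    n_hemispheres: int = 2
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_dict(self) -> dict:
        d = {
            "task": asdict(self.task),
            "agent": asdict(self.agent),
            "lfp": asdict(self.lfp),
            "stim": asdict(self.stim) if self.stim else None,
            "stim_effect": asdict(self.stim_effect) if self.stim_effect else None,
            "n_subjects": self.n_subjects,
            "n_hemispheres": self.n_hemispheres,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_SECTION_TYPES = {
    "task": TaskConfig,
    "agent": AgentConfig,
    "lfp": LfpGenConfig,
    "stim": StimScheduleConfig,
    "stim_effect": StimBehaviorEffect,
}
_TOP_KEYS = set(_SECTION_TYPES) | {"n_subjects", "n_hemispheres", "n_perm", "seed"}


def _build_section(name: str, cls, payload: dict):
    import dataclasses

    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(
            f"config section '{name}' has unknown key(s): {', '.join(sorted(unknown))}"
        )
    payload = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in payload.items()
    }
    return cls(**payload)


def load_config(path: Path | str) -> AnalysisConfig:
    """Load and validate a YAML analysis configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if raw.get(name) is not None:
            kwargs[name] = _build_section(name, cls, raw[name])
    for key in ("n_subjects", "n_hemispheres", "n_perm", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    return AnalysisConfig(**kwargs)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> wall seconds
    outputs: list = field(default_factory=list)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.stages[name] = round(time.perf_counter() - self.t0, 3)
                return False

        return _Timer()

    def add_outputs(self, files) -> None:
        self.outputs.extend(str(f) for f in files)

    def write(self, path: Path | str) -> Path:
        """Atomic write: serialize to a temp file, then rename."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "version": self.version,
                    "seed": self.seed,
                    "stages": self.stages,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
            )
        os.replace(tmp, path)
        return path
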