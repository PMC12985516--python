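"""Structured run configuration.

A run is described by a small YAML file: top-level analysis settings plus a
nested ``cea`` section whose keys are :class:`~npcstage.cea.CEAParameters`
field names. Everything has a default, so an empty file (or no file) is a
valid configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cea import CEAParameters


@dataclass(frozen=True)
class RunConfig:
    cutoff: int = 2
    continuity_correction: bool = True
    ci_method: str = "wilson"
    seed: int = 0
    output_dir: str = "results"
    cea: CEAParameters = field(default_factory=CEAParameters)

    def __post_init__(self) -> None:
        if self.cutoff not in (1, 2, 3, 4):
            raise ValueError(f"cutoff must be in 1..4, got {self.cutoff}")
        if self.ci_method != "wilson":
            raise ValueError(f"unsupported ci_method {self.ci_method!r}")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides.

    Unknown keys fail loudly; keyword overrides win over the file.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            data = loaded
    data.update({k: v for k, v in overrides.items() if v is not None})
    cea_data = data.pop("cea", {}) or {}
    valid_cea = {f.name for f in dataclasses.fields(CEAParameters)}
    unknown = set(cea_data) - valid_cea
    if unknown:
        raise ValueError(f"unknown cea parameters: {sorted(unknown)}")
    valid_run = {f.name for f in dataclasses.fields(RunConfig)} - {"cea"}
    unknown = set(data) - valid_run
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(cea=CEAParameters(**cea_data), **data)
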